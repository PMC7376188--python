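import csv
from pathlib import Path

import pytest

from strmps.locus_model import load_builtin_loci

DATA = Path(__file__).resolve().parents[1] / "src" / "strmps" / "data"


@pytest.fixture(scope="session")
def loci():
    return load_builtin_loci()


@pytest.fixture(scope="session")
def novel_rows():
    """The shipped novel-allele fixture (locus, lb_allele, name, count)."""
    with (DATA / "novel_alleles.tsv").open(encoding="utf-8") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))
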