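import io

import pytest

from ystrkit.forensic import ClassSpectrum
from ystrkit.io import get_panel, write_haplotype_table
from ystrkit.simulate import table_from_spectrum


TREE_TSV = """\
haplogroup\tparent\tsnp\tancestral\tderived
Y\t\t\t\t
CT\tY\tM168\tC\tT
DE\tCT\tM145\tG\tA
D\tDE\tM174\tT\tC
K\tCT\tM9\tC\tG
O\tK\tM175\tA\tC
O1\tO\tM119\tA\tC
O2\tO\tM122\tT\tC
Q\tK\tM242\tC\tT
"""


@pytest.fixture
def tree_tsv() -> str:
    """Small synthetic Y-haplogroup hierarchy (invented SNP alleles)."""
    return TREE_TSV


@pytest.fixture
def small_table():
    """20 GE26 samples: 16 singletons + 2 pairs."""
    return table_from_spectrum(ClassSpectrum(20, {1: 16, 2: 2}),
                               panel="GE26", seed=11)


@pytest.fixture
def small_table_text(small_table) -> str:
    buf = io.StringIO()
    write_haplotype_table(small_table, buf)
    return buf.getvalue()


@pytest.fixture
def mh9_panel():
    return get_panel("MH9")


@pytest.fixture
def ge26_panel():
    return get_panel("GE26")
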