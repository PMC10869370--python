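from __future__ import annotations

import textwrap
from pathlib import Path

import pytest

from digenicloh import synthetic as syn

VCF_HEADER = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##FILTER=<ID=PASS,Description="All filters passed">
    ##FILTER=<ID=weak_evidence,Description="Weak evidence">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
    ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR
    """
)


@pytest.fixture
def make_vcf(tmp_path):
    """Write VCF body lines under the standard single-sample header."""

    counter = {"n": 0}

    def _write(body_lines: list[str], name: str | None = None) -> Path:
        counter["n"] += 1
        path = tmp_path / (name or f"calls{counter['n']}.vcf")
        path.write_text(VCF_HEADER + "".join(line + "\n" for line in body_lines))
        return path

    return _write


@pytest.fixture(scope="session")
def sbs_matrix_3():
    """Three well-separated synthetic substitution signatures."""
    return syn.random_signature_matrix("SBS96", 3, seed=11)


@pytest.fixture(scope="session")
def id_matrix_3():
    return syn.random_signature_matrix("ID83", 3, seed=12)
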