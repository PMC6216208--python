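"""Shared fixtures: the published five-SNP PD-risk locus report used as a
known-answer benchmark, plus small helper factories."""

from __future__ import annotations

import pytest

from gwascreen import GenotypeCounts

# Published case-control genotype counts for five SNPs in the RIT2 locus
# (988 PD cases / 2521 controls, Japanese cohort), ordered
# (hom-minor, het, hom-major), with the printed per-SNP statistics used as
# known answers.  rs4130047 controls have one sample missing (2520/2521
# genotyped, call rate 0.9996).
RIT2_ROWS = [
    # snp_id, chrom, pos, minor, major, case triple, control triple, miss_case, miss_ctrl
    ("rs879215", "18", 40557661, "T", "C", (19, 207, 762), (58, 704, 1759), 0, 0),
    ("rs4243267", "18", 40656531, "G", "T", (99, 427, 462), (340, 1184, 997), 0, 0),
    ("rs4441358", "18", 40657643, "G", "A", (97, 428, 463), (340, 1182, 999), 0, 0),
    ("rs4536548", "18", 40659924, "A", "G", (99, 428, 461), (340, 1184, 997), 0, 0),
    ("rs4130047", "18", 40678235, "C", "T", (176, 477, 335), (330, 1172, 1018), 0, 1),
]

RIT2_EXPECTED = {
    # snp_id: (maf_case, maf_control, p_trend, p_hwd_control)
    "rs879215": (0.124, 0.1626, 4.59e-5, 0.2146),
    "rs4243267": (0.3163, 0.3697, 2.53e-5, 0.7324),
    "rs4441358": (0.3148, 0.3693, 1.69e-5, 0.7648),
    "rs4536548": (0.3168, 0.3697, 3.01e-5, 0.7324),
    "rs4130047": (0.4195, 0.3635, 1.37e-5, 0.8296),
}


@pytest.fixture(scope="session")
def rit2_rows() -> list[GenotypeCounts]:
    return [
        GenotypeCounts(
            snp_id=s, chrom=c, pos=p, minor_allele=mi, major_allele=ma,
            case_counts=ca, control_counts=co, case_missing=mc, control_missing=mo,
        )
        for s, c, p, mi, ma, ca, co, mc, mo in RIT2_ROWS
    ]


@pytest.fixture(scope="session")
def rit2_expected() -> dict:
    return RIT2_EXPECTED


@pytest.fixture()
def rit2_tsv(tmp_path, rit2_rows):
    """The locus report written in the genotype-count TSV dialect."""
    from gwascreen.io import write_genotype_counts

    path = tmp_path / "rit2_counts.tsv"
    write_genotype_counts(rit2_rows, path)
    return path
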