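import numpy as np
import pytest

from crossase.design import default_design
from crossase.formats import write_vcf
from crossase.selection import InformativeSNP, Strategy


@pytest.fixture
def design():
    return default_design()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=FS,Number=1,Type=Float,Description="fs">\n'
    '##INFO=<ID=QD,Number=1,Type=Float,Description="qd">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n'
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">\n'
)


def make_vcf(path, lines, samples=("KNP_M", "KNP_F", "LR_M", "LR_F")):
    """Write a minimal VCF from pre-formatted data lines."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        for line in lines:
            fh.write(line + "\n")
    return path


def informative_snp(chrom="1", pos=100, gene="G1", ref="A", knp="A", lr="G",
                    strategy=Strategy.I):
    return InformativeSNP(chrom, pos, frozenset([gene]), ref, knp, lr, strategy)


# Ratio cells of the printed nine-gene worked example, one row per gene:
# (gene, ratios in the K-dam cross male/female pools, then the reciprocal
# cross), with (paternal, maternal) count pairs that reproduce each printed
# ratio at three decimals.
WORKED_EXAMPLE = [
    ("NUSAP1", ((30, 0), (30, 0), (30, 0), (30, 0))),
    ("FAM83H", ((30, 0), (30, 0), (0, 30), (0, 30))),
    ("SLC6A17", ((35, 4), (24, 12), (3, 29), (27, 55))),
    ("MANBA", ((0, 30), (0, 30), (30, 0), (30, 0))),
    ("PEG10", ((30, 0), (30, 0), (30, 0), (30, 0))),
    ("ENSSSCG00000010703", ((24, 12), (13, 4), (11, 28), (3, 13))),
    ("ENSSSCG00000010719", ((28, 8), (23, 2), (4, 19), (5, 20))),
    ("TFR2", ((8, 28), (0, 20), (18, 2), (8, 3))),
    ("PPFIBP1", ((2, 5), (4, 13), (0, 25), (3, 7))),
]

WORKED_EXAMPLE_RATIOS = {
    "NUSAP1": (1.0, 1.0, 1.0, 1.0),
    "FAM83H": (1.0, 1.0, 0.0, 0.0),
    "SLC6A17": (0.897, 0.667, 0.094, 0.329),
    "MANBA": (0.0, 0.0, 1.0, 1.0),
    "PEG10": (1.0, 1.0, 1.0, 1.0),
    "ENSSSCG00000010703": (0.667, 0.765, 0.282, 0.188),
    "ENSSSCG00000010719": (0.778, 0.92, 0.174, 0.2),
    "TFR2": (0.222, 0.0, 0.9, 0.727),
    "PPFIBP1": (0.286, 0.235, 0.0, 0.3),
}

WORKED_EXAMPLE_PATTERNS = {
    "NUSAP1": "paternal_biased",
    "FAM83H": "allele_dominant",
    "SLC6A17": "allele_dominant",
    "MANBA": "allele_dominant",
    "PEG10": "paternal_biased",
    "ENSSSCG00000010703": "allele_dominant",
    "ENSSSCG00000010719": "allele_dominant",
    "TFR2": "allele_dominant",
    "PPFIBP1": "maternal_biased",
}
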