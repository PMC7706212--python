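"""Panel definitions: the 156-gene tumor panel, the POLE add-on, BED import.

Real amplicon coordinates for the custom panel are not distributed, so the
default panel lays each gene out on a synthetic coordinate grid (one
contiguous target region per gene). That is sufficient for every
downstream rule, all of which key on (chrom, pos, ref, alt) and gene
symbol rather than on true genomic context.
"""

from __future__ import annotations

from .model import PanelDefinition, ValidationError

# Genes whose identity matters downstream: PI3-kinase pathway, TP53,
# mismatch repair, and the polymerase add-on target.
PI3K_GENES = ("PTEN", "PIK3CA", "PIK3R1", "PIK3R3")
MMR_GENES = ("MLH1", "MSH2", "MSH6", "PMS2")
TP53 = "TP53"
POLE = "POLE"

# A representative slice of recurrently mutated solid-tumor genes to fill
# the panel out to 156 symbols; passenger variants are scattered across
# these uniformly by region length.
_FILLER_GENES = (
    "AKT1", "AKT2", "ALK", "APC", "AR", "ARID1A", "ARID1B", "ARID5B", "ATM",
    "ATR", "AXIN1", "BAP1", "BARD1", "BCL2", "BRAF", "BRCA1", "BRCA2",
    "BRIP1", "CCND1", "CCNE1", "CDH1", "CDK4", "CDK6", "CDKN1B", "CDKN2A",
    "CHEK1", "CHEK2", "CIC", "CREBBP", "CSF1R", "CTCF", "CTNNB1", "DDR2",
    "DNMT3A", "EGFR", "EP300", "ERBB2", "ERBB3", "ERBB4", "ESR1",
    "EZH2", "FANCA", "FANCC", "FANCD2", "FBXW7", "FGFR1", "FGFR2", "FGFR3",
    "FGFR4", "FLT3", "FOXA1", "FOXL2", "GATA3", "GNA11", "GNAQ", "GNAS",
    "HNF1A", "HRAS", "IDH1", "IDH2", "IGF1R", "JAK1", "JAK2", "JAK3",
    "KDM6A", "KDR", "KEAP1", "KIT", "KMT2A", "KMT2C", "KMT2D", "KRAS",
    "MAP2K1", "MAP2K4", "MAP3K1", "MAPK1", "MAX", "MDM2", "MDM4", "MED12",
    "MET", "MITF", "MRE11", "MTOR", "MYC", "MYCN", "MYD88",
    "NBN", "NF1", "NF2", "NFE2L2", "NOTCH1", "NOTCH2", "NOTCH3", "NPM1",
    "NRAS", "NTRK1", "NTRK2", "NTRK3", "PALB2", "PDGFRA", "PDGFRB",
    "PIK3C2B", "PIK3R2", "POLD1", "PPP2R1A", "PRKAR1A", "PTCH1", "PTPN11",
    "RAD50", "RAD51", "RAD51B", "RAD51C", "RAD51D", "RAF1", "RB1", "RET",
    "RHOA", "RICTOR", "RNF43", "ROS1", "RPTOR", "SDHA", "SDHB", "SDHC",
    "SDHD", "SETD2", "SF3B1", "SMAD2", "SMAD3", "SMAD4", "SMARCA4",
    "SMARCB1", "SMO", "SOX2", "SPOP", "STAG2", "STK11", "TERT",
    "TET2", "TGFBR2", "TSC1", "TSC2", "U2AF1", "VHL", "WT1", "ZNF217",
)

ECCP_PANEL_ID = "ECCP-156"
POLE_PANEL_ID = "POLE-addon"

_GENE_SPAN = 30_000
_GENE_LENGTH = 4_000


def _layout(genes: tuple[str, ...], offset: int = 0) -> dict[str, tuple[str, int, int]]:
    regions = {}
    for i, gene in enumerate(genes):
        chrom = f"chr{(i % 22) + 1}"
        start = 1_000_000 + (i + offset) * _GENE_SPAN
        regions[gene] = (chrom, start, start + _GENE_LENGTH - 1)
    return regions


def default_panel() -> PanelDefinition:
    """The 156-gene tumor panel on synthetic coordinates."""
    genes = PI3K_GENES + MMR_GENES + (TP53,) + _FILLER_GENES
    assert len(genes) == 156, len(genes)
    gene_regions = _layout(genes)
    return PanelDefinition(
        panel_id=ECCP_PANEL_ID,
        gene_symbols=frozenset(genes),
        target_regions=sorted(gene_regions.values()),
        amplicon_count=1509,
        covered_kb=float(len(genes) * _GENE_LENGTH) / 1000.0,
        exonic_coverage_fraction=0.95,
        gene_regions=gene_regions,
    )


def pole_panel() -> PanelDefinition:
    """The POLE add-on assay: 108 amplicons, 11.19 kb, 92.74% exonic coverage."""
    gene_regions = {POLE: ("chr12", 133_200_000, 133_263_951)}
    return PanelDefinition(
        panel_id=POLE_PANEL_ID,
        gene_symbols=frozenset({POLE}),
        target_regions=sorted(gene_regions.values()),
        amplicon_count=108,
        covered_kb=11.19,
        exonic_coverage_fraction=0.9274,
        gene_regions=gene_regions,
    )


def read_panel_bed(path, panel_id: str, gene_symbols=None) -> PanelDefinition:
    """Read target regions from a BED file.

    BED is 0-based half-open; intervals are converted to the internal
    1-based closed convention (start + 1, end). The optional 4th BED
    column supplies gene symbols.
    """
    regions: list[tuple[str, int, int]] = []
    genes: set[str] = set(gene_symbols or ())
    gene_regions: dict[str, tuple[str, int, int]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{path}:{lineno}: BED line needs >= 3 columns")
            chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
            if end0 <= start0:
                raise ValidationError(f"{path}:{lineno}: empty BED interval")
            region = (chrom, start0 + 1, end0)
            regions.append(region)
            if len(fields) >= 4 and fields[3] not in (".", ""):
                genes.add(fields[3])
                gene_regions.setdefault(fields[3], region)
    if not genes:
        raise ValidationError(f"{path}: no gene symbols in BED and none supplied")
    return PanelDefinition(
        panel_id=panel_id,
        gene_symbols=frozenset(genes),
        target_regions=regions,
        gene_regions=gene_regions,
    )
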