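"""Marker-gene quantification: qPCR copy numbers, cell conversions and
metagenomic community fractions.

Methanotroph abundance in mound material is measured three ways, all
converging on "cells per gram dry material" or "fraction of the
community":

* qPCR of the *pmoA* gene (particulate methane monooxygenase subunit)
  and of the 16S rRNA gene, calibrated against standard dilution series
  (:func:`fit_standard_curve`, :func:`quantify_copies_per_gram`), with
  copy-to-cell conversion assuming on average 2 *pmoA* copies per
  methanotroph cell and 4.2 16S rRNA gene copies per bacterial cell
  (:func:`copies_to_cells`);
* shotgun-metagenomic read counts of *pmoA*/*mmoX*, RPKM-normalised and
  divided by the mean RPKM of 14 universal single-copy ribosomal marker
  genes (:func:`marker_fraction_metagenome`);
* 16S rRNA amplicon tables with externally supplied methanotroph ASV
  labels (:func:`asv_methanotroph_fraction`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "QpcrSample",
    "QpcrQuantification",
    "AbundanceEstimate",
    "MarkerCount",
    "SINGLE_COPY_MARKERS",
    "COPIES_PER_CELL",
    "fit_standard_curve",
    "quantify_copies_per_gram",
    "copies_to_cells",
    "marker_fraction_metagenome",
    "asv_methanotroph_fraction",
    "simulate_marker_counts",
]

#: Default marker-gene copies per cell used for cell-number conversion.
COPIES_PER_CELL = {"pmoA": 2.0, "16S": 4.2}

#: The 14 universal single-copy ribosomal protein genes used for
#: community-size normalisation of metagenomic read counts.
SINGLE_COPY_MARKERS = (
    "rplB", "rplC", "rplD", "rplE", "rplF", "rplN", "rplP",
    "rpsB", "rpsC", "rpsE", "rpsJ", "rpsM", "rpsS", "rpsH",
)


@dataclass
class StandardCurve:
    """qPCR calibration line Cq = slope·log10(copies) + intercept."""

    slope: float  # Cq per log10(copies); negative
    intercept: float  # Cq
    efficiency: float  # 10^(-1/slope) - 1
    r2: float
    n_levels: int
    cq_min: float  # Cq of the most concentrated standard
    cq_max: float  # Cq of the most dilute standard (detection limit)
    assay_id: Optional[str] = None
    gene: Optional[str] = None
    qc_pass: bool = True
    qc_flags: List[str] = field(default_factory=list)

    def copies_at(self, cq: float) -> float:
        """Copies per reaction implied by a Cq value."""
        return 10.0 ** ((cq - self.intercept) / self.slope)


@dataclass
class QpcrSample:
    """Sample-level qPCR record (triplicate Cq values plus extraction metadata)."""

    cq_replicates: Sequence[float]
    dilution_factor: float = 1.0
    eluate_volume: float = 100.0  # µl
    template_volume: float = 1.0  # µl
    dry_mass_extracted: float = 0.25  # g
    sample_id: Optional[str] = None
    assay_id: Optional[str] = None
    gene: Optional[str] = None

    def __post_init__(self):
        if len(self.cq_replicates) < 1:
            raise ValueError("need >= 1 Cq replicate")
        if min(self.dilution_factor, self.eluate_volume, self.template_volume) <= 0:
            raise ValueError("dilution factor and volumes must be positive")
        if self.dry_mass_extracted <= 0:
            raise ValueError("dry_mass_extracted must be positive")


@dataclass
class QpcrQuantification:
    """Back-calculated copies per gram with QC flags."""

    copies_per_g: float
    copies_per_reaction: float
    mean_cq: Optional[float]
    below_detection: bool = False
    flags: List[str] = field(default_factory=list)


@dataclass
class AbundanceEstimate:
    """Gene copies, derived cell numbers, and (optionally) relative abundance."""

    gene: str
    copies_per_g: float
    cells_per_g: float
    copies_per_cell: float
    relative_abundance: Optional[float] = None


@dataclass
class MarkerCount:
    """Read count of one marker gene in one metagenome."""

    gene: str
    reads: float
    gene_length: float  # bp
    total_reads: float

    def __post_init__(self):
        if self.reads < 0 or self.total_reads <= 0 or self.gene_length <= 0:
            raise ValueError("counts must be >= 0 and lengths/totals positive")

    @property
    def rpkm(self) -> float:
        """Reads per kilobase of gene per million sequenced reads."""
        return self.reads / (self.gene_length / 1e3 * self.total_reads / 1e6)


def fit_standard_curve(
    dilution_points: Sequence[Tuple[float, float]],
    assay_id: Optional[str] = None,
    gene: Optional[str] = None,
    efficiency_threshold: float = 0.70,
    r2_threshold: float = 0.98,
) -> StandardCurve:
    """Fit a qPCR calibration curve from (log10 copies, Cq) pairs.

    OLS of Cq on log10(copies).  The amplification efficiency is
    10^(−1/slope) − 1 (a perfect doubling per cycle has slope −3.32 and
    efficiency 1.0).  QC flags are raised — but the curve still returned
    — when efficiency ≤ 70% or r² ≤ 0.98, the acceptance thresholds used
    for the field assays.
    """
    pts = [(float(x), float(c)) for x, c in dilution_points]
    levels = {x for x, _ in pts}
    if len(levels) < 3:
        raise ValueError("need >= 3 distinct dilution levels")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    res = stats.linregress(x, y)
    if res.slope >= 0:
        raise ValueError("calibration slope must be negative (Cq falls with template)")
    efficiency = 10.0 ** (-1.0 / res.slope) - 1.0
    r2 = float(res.rvalue**2)
    flags = []
    if efficiency <= efficiency_threshold:
        flags.append(f"low_efficiency ({efficiency:.2f} <= {efficiency_threshold})")
    if r2 <= r2_threshold:
        flags.append(f"low_r2 ({r2:.4f} <= {r2_threshold})")
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        efficiency=float(efficiency),
        r2=r2,
        n_levels=len(levels),
        cq_min=float(y.min()),
        cq_max=float(y.max()),
        assay_id=assay_id,
        gene=gene,
        qc_pass=not flags,
        qc_flags=flags,
    )


def quantify_copies_per_gram(
    sample: QpcrSample,
    curve: StandardCurve,
    replicate_sd_threshold: float = 0.5,
    require_qc: bool = True,
) -> QpcrQuantification:
    """Back-calculate gene copies per g dry material from sample Cq values.

    copies/reaction = 10^((mean Cq − intercept)/slope), scaled by the
    dilution factor and the eluate/template volume ratio, per gram of
    material extracted.  Non-amplifying samples (all-NaN Cq) are reported
    as below detection at the limit implied by the most dilute standard,
    not as zero; Cq values outside the calibrated range are flagged but
    still quantified.
    """
    if require_qc and not curve.qc_pass:
        raise ValueError(f"calibration curve failed QC: {curve.qc_flags}")
    cq = np.asarray(sample.cq_replicates, dtype=float)
    flags = []
    scale = (
        sample.dilution_factor
        * (sample.eluate_volume / sample.template_volume)
        / sample.dry_mass_extracted
    )
    if np.all(np.isnan(cq)):
        limit = curve.copies_at(curve.cq_max) * scale
        return QpcrQuantification(
            copies_per_g=limit,
            copies_per_reaction=curve.copies_at(curve.cq_max),
            mean_cq=None,
            below_detection=True,
            flags=["non_amplifying"],
        )
    if np.any(np.isnan(cq)):
        flags.append("dropout_replicates")
        cq = cq[~np.isnan(cq)]
    if cq.size >= 2 and float(np.std(cq, ddof=1)) > replicate_sd_threshold:
        flags.append(f"replicate_sd>{replicate_sd_threshold}")
    mean_cq = float(np.mean(cq))
    if not curve.cq_min <= mean_cq <= curve.cq_max:
        flags.append("cq_outside_calibrated_range")
    copies_rxn = curve.copies_at(mean_cq)
    return QpcrQuantification(
        copies_per_g=copies_rxn * scale,
        copies_per_reaction=copies_rxn,
        mean_cq=mean_cq,
        below_detection=False,
        flags=flags,
    )


def copies_to_cells(
    copies_per_g: float,
    gene: str,
    copies_per_cell: Optional[float] = None,
    total_cells_per_g: Optional[float] = None,
) -> AbundanceEstimate:
    """Convert gene copies per gram to cells per gram.

    Divides by the per-cell copy number of the marker: 2 for *pmoA*,
    4.2 for the 16S rRNA gene (overridable).  When a paired total cell
    count is supplied, the relative abundance cells/total is attached.
    """
    if copies_per_g < 0:
        raise ValueError("copies_per_g must be >= 0")
    if copies_per_cell is None:
        try:
            copies_per_cell = COPIES_PER_CELL[gene]
        except KeyError:
            raise ValueError(
                f"unknown gene {gene!r}: supply copies_per_cell explicitly"
            ) from None
    cells = copies_per_g / copies_per_cell
    rel = None
    if total_cells_per_g is not None:
        if total_cells_per_g <= 0:
            raise ValueError("total_cells_per_g must be positive")
        rel = cells / total_cells_per_g
    return AbundanceEstimate(
        gene=gene,
        copies_per_g=copies_per_g,
        cells_per_g=cells,
        copies_per_cell=copies_per_cell,
        relative_abundance=rel,
    )


def marker_fraction_metagenome(
    counts: Sequence[MarkerCount],
    copies_per_genome: float = 2.0,
    target_genes: Sequence[str] = ("pmoA", "mmoX"),
) -> Dict[str, float]:
    """Community fraction carrying each methane monooxygenase gene.

    Each target gene's RPKM is divided by the mean RPKM of the 14
    universal single-copy markers present in ``counts``; the *pmoA*
    fraction is further divided by ``copies_per_genome`` (methanotroph
    genomes typically carry two *pmo* operon copies; *mmoX* is treated
    as single-copy).  Returns per-gene fractions plus their sum under
    ``"combined"``.
    """
    if copies_per_genome <= 0:
        raise ValueError("copies_per_genome must be positive")
    single_copy = [c for c in counts if c.gene in SINGLE_COPY_MARKERS]
    if not single_copy or all(c.reads == 0 for c in single_copy):
        raise ValueError("no single-copy marker with reads > 0")
    mean_sc_rpkm = float(np.mean([c.rpkm for c in single_copy]))
    by_gene = {}
    for c in counts:
        if c.gene in target_genes:
            frac = c.rpkm / mean_sc_rpkm
            if c.gene == "pmoA":
                frac /= copies_per_genome
            by_gene[c.gene] = by_gene.get(c.gene, 0.0) + frac
    by_gene["combined"] = float(sum(by_gene.values()))
    return by_gene


def asv_methanotroph_fraction(asv_table: pd.DataFrame, methanotroph_labels) -> pd.Series:
    """Per-sample fraction of reads in methanotroph-labelled ASVs.

    ``asv_table`` has ASV ids as the index and samples as columns;
    ``methanotroph_labels`` is a set of ids (must be a subset of the
    index).  The fraction is labelled reads over all reads per sample.
    """
    labels = set(methanotroph_labels)
    unknown = labels - set(asv_table.index)
    if unknown:
        raise ValueError(f"labels not in ASV table: {sorted(unknown)[:5]}")
    if (asv_table < 0).any().any():
        raise ValueError("negative ASV counts")
    totals = asv_table.sum(axis=0)
    if (totals == 0).any():
        empty = list(totals.index[totals == 0])
        raise ValueError(f"sample(s) with zero total reads: {empty}")
    labelled = asv_table.loc[sorted(labels)].sum(axis=0) if labels else 0.0 * totals
    return labelled / totals


def simulate_marker_counts(
    methanotroph_fraction: float = 0.002,
    seed: int = 0,
    total_reads: float = 7.66e7,
    mean_depth_rpk: float = 100.0,
    pmoa_copies_per_genome: float = 2.0,
    gene_lengths: Optional[Dict[str, float]] = None,
) -> List[MarkerCount]:
    """Synthetic metagenomic marker counts for a community with a known
    methanotroph fraction.

    Every genome carries one copy of each of the 14 single-copy
    ribosomal markers; a fraction of genomes additionally carries
    ``pmoa_copies_per_genome`` copies of *pmoA* (soluble-MMO *mmoX* is
    left at zero).  Expected reads per gene are proportional to
    (carrier fraction × copies × gene length); Poisson noise emulates
    read sampling.
    """
    if not 0 <= methanotroph_fraction <= 1:
        raise ValueError("methanotroph_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    lengths = {
        "pmoA": 750.0,
        "mmoX": 1600.0,
        **{g: float(L) for g, L in zip(SINGLE_COPY_MARKERS, np.linspace(600, 1800, 14))},
    }
    if gene_lengths:
        lengths.update(gene_lengths)
    counts = []
    for gene in SINGLE_COPY_MARKERS:
        lam = mean_depth_rpk * lengths[gene] / 1e3 * total_reads / 1e6
        counts.append(
            MarkerCount(gene=gene, reads=float(rng.poisson(lam)),
                        gene_length=lengths[gene], total_reads=total_reads)
        )
    lam_pmoa = (
        methanotroph_fraction * pmoa_copies_per_genome
        * mean_depth_rpk * lengths["pmoA"] / 1e3 * total_reads / 1e6
    )
    counts.append(
        MarkerCount(gene="pmoA", reads=float(rng.poisson(lam_pmoa)),
                    gene_length=lengths["pmoA"], total_reads=total_reads)
    )
    counts.append(
        MarkerCount(gene="mmoX", reads=0.0, gene_length=lengths["mmoX"],
                    total_reads=total_reads)
    )
    return counts
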