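"""Pooled-sequencing population genotyping and Nei genetic distances.

Population genotypes are represented as per-locus reference-allele
frequencies estimated from the allelic-depth (AD) field of a VCF: for a
biallelic SNP, ``f = AD_ref / (AD_ref + AD_alt)``.  Calls below a depth
threshold are treated as missing, then loci and samples with excessive
missingness are dropped.  Pairwise divergence between populations uses
Nei's (1972) standard genetic distance

    D = -ln( Jxy / sqrt(Jx * Jy) )

with the identity sums accumulated over biallelic loci complete in both
members of a pair (pairwise deletion).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .matrix import AlleleFrequencyTable, FilterThresholds, LabeledDistanceMatrix

__all__ = [
    "FilterReport",
    "freqs_from_vcf",
    "aggregate_populations",
    "nei_distance_matrix",
    "cluster_by_threshold",
]

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Counts of what the depth/missingness filters removed."""

    n_sites_read: int = 0
    n_loci_dropped: int = 0
    n_samples_dropped: int = 0
    dropped_loci: list[str] = field(default_factory=list)
    dropped_samples: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "n_sites_read": self.n_sites_read,
            "n_loci_dropped": self.n_loci_dropped,
            "n_samples_dropped": self.n_samples_dropped,
            "dropped_loci": list(self.dropped_loci),
            "dropped_samples": list(self.dropped_samples),
        }


class VcfCapabilityError(RuntimeError):
    """The VCF lacks a FORMAT field required for frequency genotyping."""


def freqs_from_vcf(vcf_path: str, thresholds: FilterThresholds | None = None
                   ) -> tuple[AlleleFrequencyTable, FilterReport]:
    """Extract reference-allele frequencies from a VCF of biallelic SNPs.

    Per (sample, site): ``f = AD_ref / (AD_ref + AD_alt)``, set missing when
    ``DP <= depth_min`` (strict depth requirement) or the AD sum is zero.
    Loci whose missing fraction reaches ``locus_missing_max`` are dropped
    first, then samples whose missing fraction reaches
    ``sample_missing_max``.

    Returns the filtered table together with a :class:`FilterReport`.
    """
    from cyvcf2 import VCF

    thresholds = thresholds or FilterThresholds()
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    if not samples:
        raise VcfCapabilityError(f"no samples in {vcf_path}")

    locus_ids: list[str] = []
    rows: list[np.ndarray] = []
    report = FilterReport()
    for rec in vcf:
        report.n_sites_read += 1
        if len(rec.ALT) != 1:
            raise ValueError(
                f"record {rec.CHROM}:{rec.POS} is not a biallelic SNP "
                f"(ALT={rec.ALT})"
            )
        ad = rec.format("AD")
        if ad is None:
            raise VcfCapabilityError(
                f"record {rec.CHROM}:{rec.POS} carries no AD FORMAT field"
            )
        ad = np.asarray(ad, dtype=float)
        ad[ad < 0] = np.nan  # cyvcf2 encodes missing AD as negative sentinels
        dp = rec.format("DP")
        if dp is None:
            dp = np.nansum(ad, axis=1)
        else:
            dp = np.asarray(dp, dtype=float).reshape(-1)
            dp[dp < 0] = np.nan
        ad_sum = ad[:, 0] + ad[:, 1]
        with np.errstate(invalid="ignore", divide="ignore"):
            f = ad[:, 0] / ad_sum
        bad = np.isnan(dp) | (dp <= thresholds.depth_min) | ~(ad_sum > 0)
        f[bad] = np.nan
        locus_ids.append(f"{rec.CHROM}:{rec.POS}")
        rows.append(f)
    if not rows:
        raise ValueError(f"no variant records in {vcf_path}")

    freq = np.column_stack(rows)  # samples x loci
    # locus filter first, then sample filter
    locus_missing = np.isnan(freq).mean(axis=0)
    keep_loci = locus_missing < thresholds.locus_missing_max
    report.dropped_loci = [l for l, k in zip(locus_ids, keep_loci) if not k]
    report.n_loci_dropped = len(report.dropped_loci)
    freq = freq[:, keep_loci]
    locus_ids = [l for l, k in zip(locus_ids, keep_loci) if k]
    if not locus_ids:
        raise ValueError("all loci removed by the missingness filter")

    sample_missing = np.isnan(freq).mean(axis=1)
    keep_samples = sample_missing < thresholds.sample_missing_max
    report.dropped_samples = [s for s, k in zip(samples, keep_samples) if not k]
    report.n_samples_dropped = len(report.dropped_samples)
    freq = freq[keep_samples]
    samples = [s for s, k in zip(samples, keep_samples) if k]
    if not samples:
        raise ValueError("all samples removed by the missingness filter")

    logger.info(
        "freqs_from_vcf: %d sites read, %d loci and %d samples dropped",
        report.n_sites_read, report.n_loci_dropped, report.n_samples_dropped,
    )
    return AlleleFrequencyTable(samples, locus_ids, freq), report


def aggregate_populations(table: AlleleFrequencyTable,
                          grouping: Mapping[str, str]) -> AlleleFrequencyTable:
    """Average allele frequencies per locus across members of each group.

    Pools samples that share a genetic background into one population
    genotype: the unweighted mean over non-missing member frequencies,
    missing only where every member is missing.
    """
    missing = [p for p in table.population_ids if p not in grouping]
    if missing:
        raise KeyError(f"populations without a group assignment: {missing}")
    groups: dict[str, list[int]] = {}
    for i, p in enumerate(table.population_ids):
        groups.setdefault(grouping[p], []).append(i)
    names = list(groups)
    out = np.full((len(names), table.n_loci), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        for g, name in enumerate(names):
            out[g] = np.nanmean(table.freq[groups[name]], axis=0)
    return AlleleFrequencyTable(names, list(table.locus_ids), out)


def nei_distance_matrix(table: AlleleFrequencyTable) -> LabeledDistanceMatrix:
    """Nei's (1972) standard genetic distance between all population pairs.

    For biallelic loci with reference frequencies ``p_l`` and ``q_l`` in the
    two populations, summed over the loci where both are present:

        Jxy = sum p*q + (1-p)(1-q);  Jx = sum p^2 + (1-p)^2;  Jy likewise
        D   = -ln( Jxy / sqrt(Jx * Jy) ), clamped below at 0.

    ``Jxy = 0`` (alleles fixed opposite at every shared locus) yields
    ``+inf`` with a warning rather than NaN.
    """
    n = table.n_populations
    if n < 2:
        raise ValueError("need at least 2 populations")
    F = table.freq
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(F[i]) & ~np.isnan(F[j])
            if not both.any():
                raise ValueError(
                    f"populations {table.population_ids[i]!r} and "
                    f"{table.population_ids[j]!r} share no complete locus"
                )
            p, q = F[i, both], F[j, both]
            jxy = np.sum(p * q + (1 - p) * (1 - q))
            jx = np.sum(p**2 + (1 - p) ** 2)
            jy = np.sum(q**2 + (1 - q) ** 2)
            if jxy == 0:
                warnings.warn(
                    f"Jxy = 0 for pair ({table.population_ids[i]}, "
                    f"{table.population_ids[j]}): distance is +inf",
                    RuntimeWarning, stacklevel=2,
                )
                d[i, j] = d[j, i] = np.inf
            else:
                d[i, j] = d[j, i] = max(0.0, -np.log(jxy / np.sqrt(jx * jy)))
    return LabeledDistanceMatrix(list(table.population_ids), d)


def cluster_by_threshold(D: LabeledDistanceMatrix, threshold: float,
                         method: str = "single"
                         ) -> list[dict]:
    """Cut a hierarchical clustering of the distance matrix at a threshold.

    Populations closer than the threshold under the chosen linkage share a
    genetic background.  Returns one record per group with its member
    labels and the maximum within-group pairwise distance.
    """
    if not D.is_complete:
        raise ValueError("matrix has missing entries; impute before clustering")
    if D.n == 1:
        return [{"members": list(D.labels), "max_within_distance": 0.0}]
    Z = linkage(squareform(D.d, checks=False), method=method)
    assign = fcluster(Z, t=threshold, criterion="distance")
    out = []
    for c in np.unique(assign):
        idx = np.where(assign == c)[0]
        sub = D.d[np.ix_(idx, idx)]
        out.append({
            "members": [D.labels[i] for i in idx],
            "max_within_distance": float(sub.max()) if len(idx) > 1 else 0.0,
        })
    return out
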