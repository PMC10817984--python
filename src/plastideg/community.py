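"""Plastisphere community statistics from ORF tables and ASV counts.

An *ORF table* is a pandas DataFrame with one row per predicted protein and
columns ``orf_id, scaffold_id, coverage, length, class, genus, is_rpsC``
plus (for composition work) one integer column per standard amino acid
(single-letter code) and optionally ``nonstandard`` for ambiguous symbols.
Scaffold read coverage serves as the abundance weight of every ORF on that
scaffold.

Community-level quantities derived from such tables:

* relative taxon frequencies from the single-copy marker RpsC (ribosomal
  protein S3), weighting each marker by scaffold coverage x protein length;
* the pooled, coverage-weighted amino-acid composition of the community
  proteome, from which two environmental proxies follow:
  - F_IVYWREL, the fraction of Ile/Val/Tyr/Trp/Arg/Glu/Leu residues, mapped
    to an optimal growth temperature by T_opt(C) = F_IVYWREL * 937 - 335;
  - Z_C, the average oxidation state of carbon, (Z + 2(nO+nS) + 3nN - nH)/nC,
    a proxy for the redox state of the environment.

Alpha diversity (Shannon in nats, bias-corrected Chao1) and coverage-based
rarefaction operate on integer ASV count vectors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, xlogy

from .errors import (
    DataWarning,
    EmptyMarkerError,
    InvalidInputError,
)
from .residues import (
    IVYWREL,
    NONSTANDARD_SYMBOLS,
    RESIDUE_COMPOSITION,
    STANDARD_RESIDUES,
    WATER,
)

__all__ = [
    "CommunityProfile",
    "AminoAcidMatrix",
    "ProxyEstimates",
    "rpsc_relative_frequency",
    "filter_rpsc_for_tree",
    "community_aa_matrix",
    "f_ivywrel",
    "t_opt",
    "protein_elemental_composition",
    "z_c",
    "community_z_c",
    "community_proxies",
    "shannon",
    "chao1",
    "goods_coverage",
    "coverage_rarefy",
    "diversity_rate_association",
]

TAXON_LEVELS = ("class", "genus")


@dataclass(frozen=True)
class CommunityProfile:
    """Relative taxon frequencies (fractions summing to 1) for one sample."""

    frequencies: pd.Series
    level: str
    weighting: str = "scaffold coverage x protein length"
    sample_id: str | None = None

    def __post_init__(self):
        total = float(self.frequencies.sum())
        if abs(total - 1.0) > 1e-9:
            raise InvalidInputError(f"frequencies sum to {total}, expected 1")
        if (self.frequencies < 0).any():
            raise InvalidInputError("frequencies must be >= 0")


@dataclass(frozen=True)
class AminoAcidMatrix:
    """Coverage-weighted residue counts pooled over a community proteome."""

    weighted_counts: pd.Series  # index: 20 standard residues
    total: float
    excluded_nonstandard: float  # weighted mass of X/B/Z/U/J/O/* symbols
    sample_id: str | None = None


@dataclass(frozen=True)
class ProxyEstimates:
    """Environmental proxies for one community."""

    f_ivywrel: float
    t_opt_c: float
    z_c: float
    sample_id: str | None = None


def _require_columns(orfs: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = [c for c in cols if c not in orfs.columns]
    if missing:
        raise InvalidInputError(f"ORF table is missing columns: {missing}")


def rpsc_relative_frequency(orfs: pd.DataFrame, level: str = "genus") -> CommunityProfile:
    """Marker-based community profile at ``level`` ('class' or 'genus').

    Each RpsC record contributes weight coverage x length; the profile is
    each taxon's summed weight over the community total.
    """
    if level not in TAXON_LEVELS:
        raise InvalidInputError(f"level must be one of {TAXON_LEVELS}")
    _require_columns(orfs, ["coverage", "length", "is_rpsC", level])
    markers = orfs[(orfs["is_rpsC"].astype(bool)) & (orfs["coverage"] > 0)]
    if markers.empty:
        raise EmptyMarkerError("no rpsC records with positive coverage")
    weights = markers["coverage"].astype(float) * markers["length"].astype(float)
    per_taxon = weights.groupby(markers[level]).sum()
    freqs = (per_taxon / per_taxon.sum()).sort_values(ascending=False)
    return CommunityProfile(frequencies=freqs, level=level)


def filter_rpsc_for_tree(
    orfs: pd.DataFrame, min_coverage: float = 10.0, min_length: int = 150
) -> pd.DataFrame:
    """RpsC records suitable for phylogenetic placement.

    Keeps markers with coverage strictly greater than ``min_coverage`` and
    length strictly greater than ``min_length`` residues; boundary values
    are excluded. Row order is preserved; an empty result is allowed.
    """
    _require_columns(orfs, ["coverage", "length", "is_rpsC"])
    mask = (
        orfs["is_rpsC"].astype(bool)
        & (orfs["coverage"] > min_coverage)
        & (orfs["length"] > min_length)
    )
    return orfs[mask]


def community_aa_matrix(orfs: pd.DataFrame) -> AminoAcidMatrix:
    """Coverage-weighted pooled residue counts over all ORFs.

    For each standard residue r, sum_i coverage_i * count_i(r). Non-standard
    symbols are excluded from both the counts and the total, and their
    weighted mass is reported separately.
    """
    _require_columns(orfs, ["coverage"])
    present = [r for r in STANDARD_RESIDUES if r in orfs.columns]
    if not present:
        raise InvalidInputError("ORF table has no residue-count columns")
    cov = orfs["coverage"].astype(float)
    if not (cov > 0).any():
        raise InvalidInputError("all-zero coverage: degenerate weighting")
    weighted = pd.Series(
        {r: float((cov * orfs[r].astype(float)).sum()) for r in present},
        name="weighted_count",
    ).reindex(list(STANDARD_RESIDUES), fill_value=0.0)
    excluded = 0.0
    if "nonstandard" in orfs.columns:
        excluded = float((cov * orfs["nonstandard"].astype(float)).sum())
    return AminoAcidMatrix(
        weighted_counts=weighted, total=float(weighted.sum()), excluded_nonstandard=excluded
    )


def f_ivywrel(matrix: AminoAcidMatrix) -> float:
    """Fraction of I/V/Y/W/R/E/L residues in the pooled community proteome."""
    if not matrix.total > 0:
        raise InvalidInputError("empty amino-acid matrix")
    return float(matrix.weighted_counts[sorted(IVYWREL)].sum() / matrix.total)


def t_opt(f: float) -> float:
    """Optimal growth temperature (C) from the thermophily proxy.

    Linear map T_opt = F_IVYWREL * 937 - 335, valid for F in [0, 1]; the
    result is not clamped, so compositions far from natural proteomes map to
    physically absurd temperatures (flagged by a warning below 0 or above
    120 C).
    """
    if not 0.0 <= f <= 1.0:
        raise InvalidInputError("F_IVYWREL must lie in [0, 1]")
    temp = f * 937.0 - 335.0
    if temp < 0.0 or temp > 120.0:
        warnings.warn(
            f"T_opt = {temp:.1f} C is outside the physically plausible range",
            DataWarning,
            stacklevel=2,
        )
    return temp


def protein_elemental_composition(
    residue_counts: dict[str, float] | pd.Series, termini: str = "plus_water"
) -> tuple[float, float, float, float, float]:
    """(C, H, N, O, S) atom counts of a protein from its residue counts.

    Residues contribute their chain (dehydrated) composition; with
    ``termini="plus_water"`` one H2O is added for the free N/C termini,
    matching the free-peptide formula. ``termini="residue_only"`` omits it,
    which is the natural convention for pooled per-residue statistics.
    """
    if termini not in ("plus_water", "residue_only"):
        raise InvalidInputError("termini must be 'plus_water' or 'residue_only'")
    totals = [0.0] * 5
    for residue, count in dict(residue_counts).items():
        if count == 0:
            continue
        if residue not in RESIDUE_COMPOSITION:
            raise InvalidInputError(f"unknown residue symbol {residue!r}")
        comp = RESIDUE_COMPOSITION[residue]
        for i in range(5):
            totals[i] += comp[i] * count
    if termini == "plus_water":
        for i in range(5):
            totals[i] += WATER[i]
    return tuple(totals)  # type: ignore[return-value]


def z_c(
    composition: tuple[float, float, float, float, float], charge: float = 0.0
) -> float:
    """Average oxidation state of carbon: (Z + 2(nO+nS) + 3nN - nH)/nC."""
    c, h, n, o, s = composition
    if not c >= 1:
        raise InvalidInputError("need at least one carbon atom")
    return (charge + 2.0 * (o + s) + 3.0 * n - h) / c


def community_z_c(orfs: pd.DataFrame, termini: str = "plus_water") -> float:
    """Coverage- and carbon-weighted mean oxidation state of carbon.

    Each protein's Z_C numerator and carbon count are weighted by its
    scaffold coverage: sum_i cov_i * num_i / sum_i cov_i * nC_i. Equivalent
    to computing Z_C of the pooled, coverage-weighted atom inventory.
    """
    _require_columns(orfs, ["coverage"])
    present = [r for r in STANDARD_RESIDUES if r in orfs.columns]
    if not present:
        raise InvalidInputError("ORF table has no residue-count columns")
    num = 0.0
    carbon = 0.0
    for _, row in orfs.iterrows():
        cov = float(row["coverage"])
        if cov == 0:
            continue
        counts = {r: float(row[r]) for r in present}
        c, h, n, o, s = protein_elemental_composition(counts, termini=termini)
        if c == 0:
            continue
        num += cov * (2.0 * (o + s) + 3.0 * n - h)
        carbon += cov * c
    if carbon == 0:
        raise InvalidInputError("community proteome contains no carbon")
    return num / carbon


def community_proxies(orfs: pd.DataFrame, termini: str = "plus_water") -> ProxyEstimates:
    """F_IVYWREL, T_opt and Z_C for one community in a single pass."""
    matrix = community_aa_matrix(orfs)
    f = f_ivywrel(matrix)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DataWarning)
        temp = t_opt(f)
    return ProxyEstimates(f_ivywrel=f, t_opt_c=temp, z_c=community_z_c(orfs, termini=termini))


# --------------------------------------------------------------------------
# Alpha diversity and coverage-based rarefaction
# --------------------------------------------------------------------------


def _as_counts(counts: Sequence[float]) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1:
        raise InvalidInputError("counts must be one-dimensional")
    if (arr < 0).any():
        raise InvalidInputError("counts must be non-negative")
    return arr


def shannon(counts: Sequence[float], base: float | None = None) -> float:
    """Shannon diversity H = -sum p ln p, in nats by default.

    ``base`` converts to another logarithm base (2 for bits, 10 for digits).
    """
    arr = _as_counts(counts)
    total = arr.sum()
    if not total > 0:
        raise InvalidInputError("empty sample: all counts zero")
    p = arr[arr > 0] / total
    h = float(-np.sum(xlogy(p, p)))
    if base is not None:
        h /= math.log(base)
    return h


def chao1(counts: Sequence[float]) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1)/(2(F2+1)).

    The bias-corrected form is defined even when no doubletons are observed.
    """
    arr = _as_counts(counts)
    if not np.allclose(arr, np.round(arr)):
        raise InvalidInputError("Chao1 requires integer counts")
    s_obs = int((arr > 0).sum())
    f1 = int((arr == 1).sum())
    f2 = int((arr == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def goods_coverage(counts: Sequence[float]) -> float:
    """Good's sample coverage estimate, 1 - F1/n."""
    arr = _as_counts(counts)
    n = arr.sum()
    if not n > 0:
        raise InvalidInputError("empty sample")
    return 1.0 - float((arr == 1).sum()) / float(n)


def _expected_coverage(counts: np.ndarray, m: int) -> float:
    """Expected Good's coverage of a size-m subsample taken without replacement.

    E[F1(m)] follows from the hypergeometric probability that a taxon with
    x copies contributes exactly one: x * C(n-x, m-1) / C(n, m).
    """
    n = int(counts.sum())
    if m >= n:
        return goods_coverage(counts)
    x = counts[counts > 0].astype(int)

    def log_choose(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    valid = (n - x) >= (m - 1)
    log_p1 = np.full(x.shape, -np.inf)
    log_p1[valid] = (
        np.log(x[valid]) + log_choose(n - x[valid], m - 1) - log_choose(n, m)
    )
    e_f1 = float(np.exp(log_p1).sum())
    return 1.0 - e_f1 / m


class RarefactionResult(NamedTuple):
    counts: np.ndarray | None  # None when the sample was dropped
    depth: int
    coverage: float


def coverage_rarefy(
    counts: Sequence[int],
    target_coverage: float = 0.99,
    seed: int | np.random.Generator | None = None,
) -> RarefactionResult:
    """Subsample a count vector to a target Good's coverage.

    Finds the smallest depth m whose *expected* coverage under
    without-replacement subsampling reaches ``target_coverage`` and draws one
    multivariate-hypergeometric subsample at that depth. This standardises
    samples at equal completeness: a sample whose full-depth coverage exceeds
    the target is subsampled *down* to the depth where the target is first
    reached. Deterministic given a seed. A sample whose full-depth coverage
    is below the target cannot be rarefied to it and is dropped
    (``counts=None``) with a warning.
    """
    if not 0.0 < target_coverage <= 1.0:
        raise InvalidInputError("target_coverage must lie in (0, 1]")
    arr = _as_counts(counts)
    if not np.allclose(arr, np.round(arr)):
        raise InvalidInputError("rarefaction requires integer counts")
    arr = arr.astype(int)
    n = int(arr.sum())
    if n < 10:
        raise InvalidInputError("need a total count of at least 10")
    full = goods_coverage(arr)
    if full < target_coverage:
        warnings.warn(
            f"full-depth coverage {full:.4f} is below target {target_coverage}; "
            "sample dropped",
            DataWarning,
            stacklevel=2,
        )
        return RarefactionResult(counts=None, depth=n, coverage=full)
    # Binary search the smallest depth reaching the target (expected coverage
    # is monotone increasing in depth for all practical count vectors).
    lo, hi = 1, n
    while lo < hi:
        mid = (lo + hi) // 2
        if _expected_coverage(arr, mid) >= target_coverage:
            hi = mid
        else:
            lo = mid + 1
    depth = lo
    if depth >= n:
        return RarefactionResult(counts=arr.copy(), depth=n, coverage=full)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sub = rng.multivariate_hypergeometric(arr, depth)
    return RarefactionResult(
        counts=sub.astype(int), depth=depth, coverage=goods_coverage(sub)
    )


class AssociationResult(NamedTuple):
    rho: float
    p_value: float
    n: int
    table: pd.DataFrame


def diversity_rate_association(
    diversity: Sequence[float], rates: Sequence[float]
) -> AssociationResult:
    """Spearman rank correlation between alpha diversity and degradation rate.

    Returns NaN (undefined-correlation sentinel) when either vector is
    constant. The paired table is returned ready for scatter plotting.
    """
    d = np.asarray(diversity, dtype=float)
    r = np.asarray(rates, dtype=float)
    if d.shape != r.shape or d.ndim != 1:
        raise InvalidInputError("diversity and rates must be paired 1-d vectors")
    if d.size < 3:
        raise InvalidInputError("need at least three paired observations")
    table = pd.DataFrame({"diversity": d, "rate": r})
    if np.ptp(d) == 0 or np.ptp(r) == 0:
        return AssociationResult(rho=float("nan"), p_value=float("nan"), n=d.size, table=table)
    res = stats.spearmanr(d, r)
    return AssociationResult(
        rho=float(res.statistic), p_value=float(res.pvalue), n=d.size, table=table
    )
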