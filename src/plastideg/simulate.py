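"""Forward simulators for every input the analysis modules consume.

Each generator is a pure function of (scenario, seed): it returns both the
observable tables (in exactly the formats the analysis modules read) and a
ground-truth sidecar holding the parameters the analysis should recover.

The simulators encode the study conditions the analyses assume:

* surface erosion — film thickness declines linearly from both faces at a
  constant rate that attenuates with water depth; mass follows thickness;
* closed-bottle BOD — cumulative O2 uptake rises first-order toward a
  plateau bounded by the theoretical oxygen demand, over a slowly drifting
  blank;
* metagenome ORF tables — taxa of equal genome size whose scaffold coverage
  scales with abundance, protein sequences drawn residue-wise from
  taxon-specific composition vectors, one RpsC marker per taxon;
* ASV counts — Dirichlet-multinomial samples whose effective concentration
  shrinks (diversity drops) as the assigned biodegradation rate rises.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .kinetics import SpecimenGeometry
from .residues import IVYWREL, RESIDUE_COMPOSITION, STANDARD_RESIDUES, TYPICAL_PROTEOME_FREQS

__all__ = [
    "ErosionScenario",
    "SimulatedErosion",
    "simulate_erosion_experiment",
    "simulate_bod_curve",
    "TaxonSpec",
    "MetagenomeScenario",
    "SimulatedMetagenome",
    "simulate_metagenome_orfs",
    "SimulatedASV",
    "simulate_asv_table",
    "default_taxa",
]


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# --------------------------------------------------------------------------
# Erosion experiments
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ErosionScenario:
    """Forward model of a film-deployment campaign.

    ``true_rate_um_day`` is the per-face thinning rate at the reference
    (shallow) site; each deployment scales it by a depth-attenuation factor.
    Defaults emulate a mid-range PHA film campaign: a 4 x 4 cm, 300 um film
    eroding at 0.75 um/day/face at the shore (an area rate of 90
    ug/cm2/day), slowed ~5x at bathyal and ~20x at abyssal depths, deployed
    for the periods used in short- and long-term seafloor tests.
    """

    polymer: str = "PHBH"
    density_g_cm3: float = 1.20
    geometry: SpecimenGeometry = field(
        default_factory=lambda: SpecimenGeometry("film", 4.0, 4.0, 300.0)
    )
    true_rate_um_day: float = 0.75
    #: (site label, depth attenuation factor, deployment days)
    deployments: tuple[tuple[str, float, int], ...] = (
        ("PJM02", 1.0, 61),
        ("BHT03", 0.18, 95),
        ("BHT08", 0.18, 250),
        ("AKR05", 0.05, 139),
        ("AMN13", 0.05, 390),
    )
    replicate_cv: float = 0.04
    measurement_sd_weight_g: float = 0.0005
    measurement_sd_thickness_um: float = 2.0
    perforation_fraction: float = 0.0
    n_replicates: int = 4

    def __post_init__(self):
        if not self.density_g_cm3 > 0:
            raise InvalidInputError("density must be > 0")
        if self.true_rate_um_day < 0:
            raise InvalidInputError("true_rate_um_day must be >= 0")
        if not 0 <= self.replicate_cv < 1:
            raise InvalidInputError("replicate_cv must lie in [0, 1)")
        if self.n_replicates < 1:
            raise InvalidInputError("n_replicates must be >= 1")
        if any(a < 0 or d <= 0 for _, a, d in self.deployments):
            raise InvalidInputError("attenuations must be >= 0 and periods > 0")
        if self.perforation_fraction < 0:
            raise InvalidInputError("perforation_fraction must be >= 0")

    def true_rate_ug_cm2_day(self, attenuation: float = 1.0) -> float:
        """Area-normalised rate implied by face erosion: V = 100 * rho * r."""
        return 100.0 * self.density_g_cm3 * self.true_rate_um_day * attenuation


class SimulatedErosion(NamedTuple):
    measurements: pd.DataFrame  # specimen measurement table (one row per specimen)
    thickness: pd.DataFrame  # long format: id, day, thickness_um
    truth: pd.DataFrame  # per-specimen true rates and per-deployment V


def simulate_erosion_experiment(
    scenario: ErosionScenario, seed: int | np.random.Generator | None = None
) -> SimulatedErosion:
    """Simulate specimen weights and thicknesses under linear face erosion.

    Thickness declines from both faces, thickness(t) = d0 - 2*r*t (truncated
    at 0); weight follows, with optional extra loss through perforation.
    Replicates vary by a mean-corrected lognormal factor of coefficient of
    variation ``replicate_cv``; Gaussian measurement noise is added to every
    recorded weight and thickness. Deterministic per seed.
    """
    rng = _rng(seed)
    geo = scenario.geometry
    rho = scenario.density_g_cm3
    face_area = geo.length_cm * geo.width_cm  # one face of one panel
    d0 = geo.thickness_um
    w0_true = rho * face_area * geo.n_panels * d0 * 1e-4
    if not w0_true > 0:
        raise InvalidInputError("scenario yields non-positive initial mass")
    sigma = math.sqrt(math.log(1.0 + scenario.replicate_cv**2))

    rows, thick_rows, truth_rows = [], [], []
    for site, atten, days in scenario.deployments:
        for rep in range(1, scenario.n_replicates + 1):
            rep_factor = (
                math.exp(rng.normal(0.0, sigma) - sigma**2 / 2.0) if sigma > 0 else 1.0
            )
            r = scenario.true_rate_um_day * atten * rep_factor
            d_final = max(0.0, d0 - 2.0 * r * days)
            face_loss_g = rho * face_area * geo.n_panels * (d0 - d_final) * 1e-4
            w_final_true = max(
                0.0, w0_true - face_loss_g * (1.0 + scenario.perforation_fraction)
            )
            sd_w = scenario.measurement_sd_weight_g
            sd_t = scenario.measurement_sd_thickness_um
            w_init = w0_true + (rng.normal(0.0, sd_w) if sd_w > 0 else 0.0)
            w_fin = max(0.0, w_final_true + (rng.normal(0.0, sd_w) if sd_w > 0 else 0.0))
            spec_id = f"{scenario.polymer}-{site}-r{rep}"
            rows.append(
                {
                    "id": spec_id,
                    "polymer": scenario.polymer,
                    "site": site,
                    "days": days,
                    "w_initial_g": w_init,
                    "w_final_g": w_fin,
                    "length_cm": geo.length_cm,
                    "width_cm": geo.width_cm,
                    "thickness_um": d0,
                    "form": geo.form,
                }
            )
            for day, d_true in ((0, d0), (days, d_final)):
                noise = rng.normal(0.0, sd_t) if sd_t > 0 else 0.0
                thick_rows.append(
                    {"id": spec_id, "day": day, "thickness_um": max(0.0, d_true + noise)}
                )
            truth_rows.append(
                {
                    "id": spec_id,
                    "site": site,
                    "days": days,
                    "true_rate_um_day_per_face": r,
                    "true_v_ug_cm2_day": scenario.true_rate_ug_cm2_day(atten),
                    "replicate_v_ug_cm2_day": 100.0 * rho * r,
                    "fully_degraded": d_final == 0.0,
                }
            )
    return SimulatedErosion(
        measurements=pd.DataFrame(rows),
        thickness=pd.DataFrame(thick_rows),
        truth=pd.DataFrame(truth_rows),
    )


# --------------------------------------------------------------------------
# BOD curves
# --------------------------------------------------------------------------


def simulate_bod_curve(
    thod_mg: float,
    k_per_day: float = 0.15,
    lag_days: float = 2.0,
    plateau_fraction: float = 1.0,
    noise_sd_mg: float = 0.05,
    days: int = 30,
    blank_drift_mg_day: float = 0.02,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate daily cumulative BOD readings for a sample and its blank.

    The sample bottle follows first-order uptake toward
    ``plateau_fraction * ThOD`` after a lag; the blank drifts linearly
    (background respiration of the seawater inoculum). Returns a long table
    (day, bod_mg, is_blank) covering days 0..``days``.
    """
    if not k_per_day > 0:
        raise InvalidInputError("k_per_day must be > 0")
    if not 0.0 <= plateau_fraction <= 1.2:
        raise InvalidInputError("plateau_fraction must lie in [0, 1.2]")
    if not thod_mg > 0:
        raise InvalidInputError("thod_mg must be > 0")
    rng = _rng(seed)
    t = np.arange(0, days + 1, dtype=float)
    blank = blank_drift_mg_day * t
    uptake = plateau_fraction * thod_mg * (1.0 - np.exp(-k_per_day * np.maximum(0.0, t - lag_days)))
    sample = blank + uptake
    if noise_sd_mg > 0:
        blank = np.maximum(0.0, blank + rng.normal(0.0, noise_sd_mg, t.size))
        sample = np.maximum(0.0, sample + rng.normal(0.0, noise_sd_mg, t.size))
    frames = [
        pd.DataFrame({"day": t, "bod_mg": sample, "is_blank": False}),
        pd.DataFrame({"day": t, "bod_mg": blank, "is_blank": True}),
    ]
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# Metagenome ORF tables
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TaxonSpec:
    """One community member: taxonomy, abundance, proteome composition."""

    tax_class: str
    genus: str
    abundance: float
    residue_freqs: tuple[float, ...]  # over STANDARD_RESIDUES, sums to 1

    def __post_init__(self):
        if not self.abundance >= 0:
            raise InvalidInputError("abundance must be >= 0")
        freqs = np.asarray(self.residue_freqs, dtype=float)
        if freqs.size != len(STANDARD_RESIDUES) or np.any(freqs < 0):
            raise InvalidInputError("residue_freqs must be 20 non-negative values")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise InvalidInputError("residue_freqs must sum to 1")
        if np.count_nonzero(freqs) < 1:
            raise InvalidInputError("degenerate residue frequency vector")


def _tilted_freqs(ivywrel_factor: float, acid_factor: float = 1.0) -> tuple[float, ...]:
    """Typical proteome frequencies with the IVYWREL set and acidic residues tilted."""
    freqs = np.array([TYPICAL_PROTEOME_FREQS[r] for r in STANDARD_RESIDUES], dtype=float)
    for i, r in enumerate(STANDARD_RESIDUES):
        if r in IVYWREL:
            freqs[i] *= ivywrel_factor
        if r in ("D", "E", "N", "Q"):
            freqs[i] *= acid_factor
    freqs /= freqs.sum()
    return tuple(freqs)


def default_taxa() -> tuple[TaxonSpec, ...]:
    """A four-member plastisphere-like community.

    Two aerobic Gammaproteobacteria dominate, with an Alphaproteobacterium
    and an anaerobic Deltaproteobacterium-like member at lower abundance;
    proteome compositions are tilted so the taxa differ in thermophily and
    redox proxies.
    """
    return (
        TaxonSpec("Gammaproteobacteria", "Colwellia", 0.40, _tilted_freqs(0.92, 1.05)),
        TaxonSpec("Gammaproteobacteria", "Agarilytica", 0.30, _tilted_freqs(1.00, 1.00)),
        TaxonSpec("Alphaproteobacteria", "Hyphomonas", 0.20, _tilted_freqs(1.08, 0.97)),
        TaxonSpec("Deltaproteobacteria", "Ca_Reidiella", 0.10, _tilted_freqs(1.18, 0.90)),
    )


@dataclass(frozen=True)
class MetagenomeScenario:
    """Community layout for simulated assemblies.

    Taxa have equal genome size (equal ORF counts) and scaffold coverage
    proportional to abundance, so marker frequencies and coverage-weighted
    composition both track abundance. Coverage noise is lognormal with
    sigma ``coverage_sigma`` per ORF scaffold; the single-copy RpsC marker
    sits on a long, well-covered scaffold and so carries much smaller
    coverage noise (``rpsc_coverage_sigma``).
    """

    taxa: tuple[TaxonSpec, ...] = field(default_factory=default_taxa)
    n_orfs: int = 2000
    coverage_scale: float = 100.0
    coverage_sigma: float = 0.5
    rpsc_coverage_sigma: float = 0.02
    rpsc_length: int = 230
    length_range: tuple[int, int] = (100, 400)

    def __post_init__(self):
        if not self.taxa:
            raise InvalidInputError("need at least one taxon")
        total = sum(t.abundance for t in self.taxa)
        if abs(total - 1.0) > 1e-9:
            raise InvalidInputError("taxon abundances must sum to 1")
        if self.n_orfs < len(self.taxa):
            raise InvalidInputError("need at least one ORF per taxon")
        if self.length_range[0] < 10 or self.length_range[1] < self.length_range[0]:
            raise InvalidInputError("invalid protein length range")

    def pooled_residue_freqs(self) -> np.ndarray:
        """Abundance-weighted mixture of taxon residue frequencies."""
        freqs = np.zeros(len(STANDARD_RESIDUES))
        for t in self.taxa:
            freqs += t.abundance * np.asarray(t.residue_freqs)
        return freqs / freqs.sum()

    def expected_f_ivywrel(self) -> float:
        pooled = self.pooled_residue_freqs()
        return float(
            sum(p for r, p in zip(STANDARD_RESIDUES, pooled) if r in IVYWREL)
        )

    def expected_z_c(self) -> float:
        """Z_C of the pooled residue mixture (chain residues, no termini)."""
        pooled = self.pooled_residue_freqs()
        num = carbon = 0.0
        for r, p in zip(STANDARD_RESIDUES, pooled):
            c, h, n, o, s = RESIDUE_COMPOSITION[r]
            num += p * (2.0 * (o + s) + 3.0 * n - h)
            carbon += p * c
        return num / carbon


class SimulatedMetagenome(NamedTuple):
    orfs: pd.DataFrame  # ORF table with residue-count columns
    sequences: dict[str, str]  # orf_id -> amino-acid sequence
    truth: dict  # analytic pooled proxies and configured abundances


def simulate_metagenome_orfs(
    scenario: MetagenomeScenario, seed: int | np.random.Generator | None = None
) -> SimulatedMetagenome:
    """Draw an ORF table, protein sequences and ground truth from a scenario.

    Residue counts and sequences are consistent by construction (sequences
    are shuffled realisations of the multinomial counts). Exactly one RpsC
    marker is emitted per taxon, labelled with that taxon.
    """
    rng = _rng(seed)
    letters = np.array(list(STANDARD_RESIDUES))
    per_taxon = scenario.n_orfs // len(scenario.taxa)
    rows: list[dict] = []
    sequences: dict[str, str] = {}

    def draw_orf(taxon: TaxonSpec, orf_id: str, length: int, coverage: float, is_rpsc: bool):
        counts = rng.multinomial(length, np.asarray(taxon.residue_freqs))
        seq_arr = np.repeat(letters, counts)
        rng.shuffle(seq_arr)
        sequences[orf_id] = "".join(seq_arr)
        row = {
            "orf_id": orf_id,
            "scaffold_id": f"scf_{orf_id}",
            "coverage": coverage,
            "length": length,
            "class": taxon.tax_class,
            "genus": taxon.genus,
            "is_rpsC": is_rpsc,
            "nonstandard": 0,
        }
        row.update({r: int(c) for r, c in zip(STANDARD_RESIDUES, counts)})
        rows.append(row)

    for t_idx, taxon in enumerate(scenario.taxa):
        mean_cov = taxon.abundance * scenario.coverage_scale
        sig = scenario.coverage_sigma
        for i in range(per_taxon):
            length = int(rng.integers(scenario.length_range[0], scenario.length_range[1] + 1))
            coverage = mean_cov * math.exp(rng.normal(0.0, sig) - sig**2 / 2.0)
            draw_orf(taxon, f"t{t_idx}_orf{i}", length, coverage, False)
        sig_r = scenario.rpsc_coverage_sigma
        rpsc_cov = mean_cov * math.exp(rng.normal(0.0, sig_r) - sig_r**2 / 2.0)
        draw_orf(taxon, f"t{t_idx}_rpsC", scenario.rpsc_length, rpsc_cov, True)

    orfs = pd.DataFrame(rows)
    truth = {
        "f_ivywrel": scenario.expected_f_ivywrel(),
        "t_opt_c": scenario.expected_f_ivywrel() * 937.0 - 335.0,
        "z_c": scenario.expected_z_c(),
        "abundances": {t.genus: t.abundance for t in scenario.taxa},
        "class_abundances": _class_abundances(scenario),
    }
    return SimulatedMetagenome(orfs=orfs, sequences=sequences, truth=truth)


def _class_abundances(scenario: MetagenomeScenario) -> dict[str, float]:
    out: dict[str, float] = {}
    for t in scenario.taxa:
        out[t.tax_class] = out.get(t.tax_class, 0.0) + t.abundance
    return out


# --------------------------------------------------------------------------
# ASV count tables
# --------------------------------------------------------------------------


class SimulatedASV(NamedTuple):
    counts: pd.DataFrame  # samples x taxa integer counts
    metadata: pd.DataFrame  # sample_id, biodegradation rate (ug/cm2/day)


def simulate_asv_table(
    n_samples: int = 50,
    n_taxa: int = 150,
    depth: int = 5000,
    rate_range: tuple[float, float] = (0.0, 120.0),
    base_diversity: float = 200.0,
    rate_effect: float = 0.3,
    base_composition: np.ndarray | None = None,
    seed: int | np.random.Generator | None = None,
) -> SimulatedASV:
    """Dirichlet-multinomial ASV counts along a biodegradation-rate gradient.

    Each sample is assigned a rate drawn uniformly from ``rate_range``; its
    community is drawn from Dirichlet(theta * base) with concentration
    theta = base_diversity / (1 + rate_effect * rate), so communities on
    fast-degrading surfaces are dominated by few taxa (low diversity) while
    slow or inert surfaces retain the diverse colonising pool. The default
    base composition is a geometric rank-abundance curve (ratio 0.97).
    ``base_diversity`` is the Dirichlet dispersion: in the limit of large
    values every sample reproduces the base composition exactly.
    """
    if n_samples < 1 or n_taxa < 2 or depth < 1:
        raise InvalidInputError("need n_samples >= 1, n_taxa >= 2, depth >= 1")
    if not base_diversity > 0 or rate_effect < 0:
        raise InvalidInputError("base_diversity must be > 0 and rate_effect >= 0")
    rng = _rng(seed)
    if base_composition is None:
        base = 0.97 ** np.arange(n_taxa)
    else:
        base = np.asarray(base_composition, dtype=float)
        if base.size != n_taxa or np.any(base < 0) or base.sum() <= 0:
            raise InvalidInputError("base_composition must be n_taxa non-negative values")
    base = base / base.sum()
    rates = rng.uniform(rate_range[0], rate_range[1], size=n_samples)
    counts = np.empty((n_samples, n_taxa), dtype=int)
    for j, rate in enumerate(rates):
        theta = base_diversity / (1.0 + rate_effect * rate)
        p = rng.dirichlet(theta * base + 1e-9)
        counts[j] = rng.multinomial(depth, p)
    sample_ids = [f"S{j:03d}" for j in range(n_samples)]
    counts_df = pd.DataFrame(
        counts, index=sample_ids, columns=[f"ASV{k:04d}" for k in range(n_taxa)]
    )
    counts_df.index.name = "sample_id"
    meta = pd.DataFrame({"sample_id": sample_ids, "rate_ug_cm2_day": rates}).set_index(
        "sample_id"
    )
    return SimulatedASV(counts=counts_df, metadata=meta)
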