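"""Synthetic-data generators emulating every input the pipelines consume.

The generators are first-class, seeded and deterministic: negative-
binomial count matrices with a planted body-mass-monotone gene subset,
tracer studies produced by the forward isotopomer model with one-pool
plasma tracer dilution, piecewise-constant OCR traces, and two-species
Gaussian flux panels with specified fold differences.  Each generator
emits the exact schema its consumer reads and a ledger of every
generating value, so recovery tests can score estimates against truth.

Default study conditions mirror the in vivo comparison the package is
built around: groups of 4 mice and 6 rats, ~2.2-fold higher glucose
production and pyruvate carboxylase flux, 3-fold higher citrate synthase
flux and 2.5-fold higher palmitate turnover in mice, with equal
gluconeogenic fraction and equal glucose-fueled oxidative fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .allometry import DEFAULT_BODY_MASS_G
from .flux_inference import TracerInfusion
from .isotopomer import EnrichmentSet, FluxParams, TracerModel, add_noise
from .respirometry import OCRTrace, StressTestParams, simulate_trace
from .species_scaling import CountMatrix

__all__ = [
    "ScalingSimConfig", "StudySimConfig", "PanelSimConfig",
    "gen_counts", "gen_tracer_study", "gen_ocr", "gen_panel",
    "DEFAULT_SPECIES_PARAMS", "DEFAULT_RA_PALMITATE",
]


# ---------------------------------------------------------------------------
# counts


@dataclass
class ScalingSimConfig:
    """Configuration of the cross-species count simulation.

    ``fold_step`` is the expression fold change between adjacent species
    in body-mass order for the planted genes (strictly log-linear in
    mass rank); across the five default species the first-to-last span
    is fold_step**4.  ``dispersion`` is the negative-binomial dispersion
    (variance = mu + dispersion * mu^2).
    """

    body_mass_g: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BODY_MASS_G))
    replicates: int = 2
    n_genes: int = 2000
    n_planted: int = 60
    fold_step: float = 4.0
    dispersion: float = 0.1
    library_size: float = 1_000_000.0
    base_mean: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted > self.n_genes:
            raise ValueError("planted genes cannot exceed total genes")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if len(self.body_mass_g) < 2:
            raise ValueError("need >= 2 species")


def _nb_sample(rng: np.random.Generator, mu: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + dispersion * mu^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def gen_counts(config: ScalingSimConfig) -> tuple[CountMatrix, list[str]]:
    """Simulate a cross-species count matrix with planted monotone genes.

    Background genes share one mean profile across species (exchangeable);
    planted genes decrease log-linearly with body-mass rank, highest in
    the smallest species.  Expected per-sample totals equal the
    configured library size.  Returns the matrix and the plant list.
    """
    rng = np.random.default_rng(config.seed)
    species = sorted(config.body_mass_g, key=config.body_mass_g.__getitem__)
    n_sp = len(species)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    planted = genes[:config.n_planted]

    base = rng.lognormal(mean=np.log(config.base_mean), sigma=1.0,
                         size=config.n_genes)
    mu = np.tile(base[:, None], (1, n_sp))
    # plants: fold_step per species step, highest in the smallest species
    steps = np.arange(n_sp - 1, -1, -1, dtype=float)
    mu[:config.n_planted, :] = (
        base[:config.n_planted, None] * config.fold_step ** steps[None, :])

    counts = {}
    species_of_sample = {}
    for j, sp in enumerate(species):
        col_mu = mu[:, j] * (config.library_size / mu[:, j].sum())
        for r in range(config.replicates):
            sample = f"{sp}_{r + 1}"
            counts[sample] = _nb_sample(rng, col_mu, config.dispersion)
            species_of_sample[sample] = sp
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(genes, name="gene_id")),
        species_of_sample=species_of_sample,
        body_mass_of_species=dict(config.body_mass_g),
    )
    return cm, planted


# ---------------------------------------------------------------------------
# tracer studies


def _default_species_params() -> dict[str, FluxParams]:
    # encode the reported in vivo effects as generating truth:
    # EGP and V_PC ~2.2x, V_CS 3x higher in mice; f_pc and r_pdh equal.
    mouse = FluxParams(v_egp=160.0, f_pc=0.9, r_pc=2.2, r_pdh=0.25,
                      x_lac=0.12, v_cs=2 * 0.9 * 160.0 / 2.2)
    rat = FluxParams(v_egp=72.0, f_pc=0.9, r_pc=2.97, r_pdh=0.25,
                     x_lac=0.12, v_cs=2 * 0.9 * 72.0 / 2.97)
    return {"mouse": mouse, "rat": rat}


DEFAULT_SPECIES_PARAMS = _default_species_params()

#: palmitate rate of appearance (lipolysis proxy), umol/(kg min): 2.5x.
DEFAULT_RA_PALMITATE = {"mouse": 25.0, "rat": 10.0}


@dataclass
class StudySimConfig:
    """Configuration of a simulated two-species in vivo tracer study."""

    params_by_species: dict[str, FluxParams] = field(
        default_factory=_default_species_params)
    ra_palmitate: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RA_PALMITATE))
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"mouse": 4, "rat": 6})
    cv: float = 0.05
    glucose_infusion: TracerInfusion = field(default_factory=lambda: TracerInfusion(
        tracer="[2H7]glucose", rate_mg_kg_min=1.0, enrichment=0.99))
    palmitate_infusion: TracerInfusion = field(default_factory=lambda: TracerInfusion(
        tracer="[U-13C16]palmitate", rate_mg_kg_min=0.8, enrichment=0.99))
    lactate_infusion: TracerInfusion = field(default_factory=lambda: TracerInfusion(
        tracer="[3-13C]lactate", rate_mg_kg_min=4.5, enrichment=0.99))
    sample_times_min: tuple[float, ...] = (100.0, 110.0, 120.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        for sp, n in self.group_sizes.items():
            if n < 1:
                raise ValueError(f"group size for {sp} must be >= 1")


_LONG_SCHEMA = ["sample_id", "species", "compartment", "analyte", "fragment",
                "ape", "time_min"]

#: wide observable name -> (compartment, analyte, fragment) in the CSV schema
OBSERVABLE_VOCAB = {
    "alanine_c3": ("liver", "alanine", "c3"),
    "malate_total": ("liver", "malate", "total"),
    "malate_c123": ("liver", "malate", "c123"),
    "glutamate_total": ("liver", "glutamate", "total"),
    "glutamate_c45": ("liver", "glutamate", "c45"),
    "glucose_m1": ("plasma", "glucose", "m1"),
    "glucose_m2": ("plasma", "glucose", "m2"),
    "glucose_f456_m1": ("plasma", "glucose", "f456_m1"),
    "glucose_f456_m2": ("plasma", "glucose", "f456_m2"),
    "glucose_m7h": ("plasma", "glucose", "m7h"),
    "palmitate_m16": ("plasma", "palmitate", "m16"),
}


def _one_pool_enrichment(infusion: TracerInfusion, ra: float) -> float:
    """Plasma enrichment implied by a true endogenous Ra (one-pool model)."""
    f = infusion.rate_umol_kg_min
    return infusion.enrichment * f / (f + ra)


def gen_tracer_study(config: StudySimConfig
                     ) -> tuple[pd.DataFrame, dict, dict]:
    """Simulate per-animal enrichment measurements for an in vivo study.

    Liver/plasma positional and mass-isotopomer enrichments come from
    the forward steady-state model; plasma tracer enrichments from the
    one-pool dilution implied by each animal's true rate of appearance.
    Multiplicative log-normal noise (coefficient of variation ``cv``) is
    applied per observable; plasma tracers are emitted at each of the
    late sampling times.

    Returns ``(long_table, protocol, ledger)`` where the long table
    follows the enrichment CSV schema, ``protocol`` the infusion
    descriptors and ``ledger`` every generating value per animal.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    ledger: dict = {"seed": config.seed, "cv": config.cv, "animals": {}}
    for sp in sorted(config.group_sizes):
        params = config.params_by_species[sp]
        ra_palm = config.ra_palmitate.get(sp)
        model = TracerModel(params)
        clean = model.observe()
        clean.glucose_m7h = _one_pool_enrichment(config.glucose_infusion,
                                                 params.v_egp)
        if ra_palm is not None:
            clean.palmitate_m16 = _one_pool_enrichment(
                config.palmitate_infusion, ra_palm)
        for i in range(config.group_sizes[sp]):
            sid = f"{sp}_{i + 1}"
            noisy = add_noise(clean, config.cv, rng)
            obs = noisy.as_dict()
            for name, value in obs.items():
                comp, analyte, frag = OBSERVABLE_VOCAB[name]
                times = (config.sample_times_min if comp == "plasma"
                         and frag in ("m7h", "m16")
                         else (config.sample_times_min[-1],))
                for t in times:
                    rows.append((sid, sp, comp, analyte, frag, value, t))
            ledger["animals"][sid] = {
                "species": sp,
                "v_egp": params.v_egp, "f_pc": params.f_pc,
                "r_pc": params.r_pc, "r_pdh": params.r_pdh,
                "v_cs": 2 * params.f_pc * params.v_egp / params.r_pc,
                "x_lac": params.x_lac,
                "ra_palmitate": ra_palm,
            }
    protocol = {
        "glucose": config.glucose_infusion,
        "palmitate": config.palmitate_infusion,
        "lactate": config.lactate_infusion,
    }
    long = pd.DataFrame(rows, columns=_LONG_SCHEMA)
    return long, protocol, ledger


# ---------------------------------------------------------------------------
# OCR traces and flux panels


def gen_ocr(params: StressTestParams, noise_sd: float, seed: int,
            n_wells: int = 6) -> list[OCRTrace]:
    """A set of simulated stress-test traces (one per well)."""
    rng = np.random.default_rng(seed)
    return [simulate_trace(params, noise_sd=noise_sd, seed=rng,
                           well=f"w{i + 1}") for i in range(n_wells)]


@dataclass
class PanelSimConfig:
    """Two-species Gaussian flux panel with a per-feature fold vector."""

    base_values: dict[str, float] = field(default_factory=lambda: {
        "egp": 72.0, "v_pc": 126.0, "v_cs": 42.0, "v_pdh": 10.5,
        "fao_flux": 31.5, "ra_palmitate": 10.0})
    fold: dict[str, float] = field(default_factory=lambda: {
        "egp": 2.2, "v_pc": 2.2, "v_cs": 3.0, "v_pdh": 3.0,
        "fao_flux": 3.0, "ra_palmitate": 2.5})
    species: tuple[str, str] = ("mouse", "rat")
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"mouse": 4, "rat": 6})
    cv: float = 0.08
    seed: int = 0


def gen_panel(config: PanelSimConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate a samples x features flux panel with species labels.

    The second species sits at the base values; the first is base x fold
    per feature; both get multiplicative Gaussian noise with coefficient
    of variation ``cv``.  Returns the panel and the generating ledger.
    """
    rng = np.random.default_rng(config.seed)
    hi, lo = config.species
    rows = []
    for sp in config.species:
        for i in range(config.group_sizes[sp]):
            row = {"sample_id": f"{sp}_{i + 1}", "species": sp}
            for feat, base in config.base_values.items():
                mean = base * (config.fold[feat] if sp == hi else 1.0)
                row[feat] = mean * max(1.0 + config.cv * rng.standard_normal(),
                                       1e-9)
            rows.append(row)
    ledger = {"base_values": dict(config.base_values),
              "fold": dict(config.fold), "cv": config.cv, "seed": config.seed}
    return pd.DataFrame(rows), ledger
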