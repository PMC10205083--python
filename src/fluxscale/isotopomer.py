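"""Steady-state positional isotopomer model of [3-13C]lactate metabolism.

The model tracks per-carbon (positional) 13C enrichment of the hepatic
pyruvate, acetyl-CoA, oxaloacetate/malate, alpha-ketoglutarate/glutamate,
PEP and triose pools under a [3-13C]lactate tracer, at metabolic and
isotopic steady state.  Reactions represented:

* pyruvate dehydrogenase (PDH): pyruvate C2,C3 -> acetyl C1,C2 (C1 lost
  as CO2); acetyl-CoA not derived from pyruvate comes from fatty-acid
  oxidation and is unlabeled,
* pyruvate carboxylase (PC): pyruvate C1-C3 -> OAA C1-C3, OAA C4 fixed
  from bicarbonate (enrichment ``x_co2``),
* citrate synthase + IDH + alpha-KGDH: acetyl C2 -> aKG C4, acetyl C1 ->
  aKG C5, OAA C4,C3,C2 -> aKG C1,C2,C3, OAA C1 lost as CO2,
* succinate/fumarate: symmetric intermediates, complete 50/50 carbon
  skeleton reversal (fumarate scrambling),
* PEPCK: OAA C1-C3 -> PEP (C4 lost as CO2); trioses inherit PEP carbons,
* gluconeogenesis: glucose assembled from two trioses drawn independently
  from the triose pool (triose C1->glucose C3/C4, C2->C2/C5, C3->C1/C6).

Pyruvate kinase and malic-enzyme back-flux are taken as zero (their flux
is small under fasting conditions), so no label returns from PEP to
pyruvate and alanine C3 reports the pyruvate C3 enrichment directly.

All enrichments are fractional (0-1) atom percent excess above natural
background; measured inputs are assumed background-corrected.

Two emergent consequences of this reaction network are used by the
inference equations and asserted in the test suite: glutamate C5 carries
no label, and malate C1 equals malate C4 at every fixed point.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ATOM_TRANSITIONS",
    "FluxParams",
    "PositionalState",
    "EnrichmentSet",
    "TracerModel",
    "steady_state",
    "observe",
    "add_noise",
    "invert_numerically",
]

#: Atom-transition table: reaction -> {(source pool, carbon): (product pool, carbon)}.
#: Carbons are 1-based.  ``None`` as product pool marks loss to CO2.  The
#: steady-state solver reads these mappings rather than hard-coding them,
#: so a disputed transition can be corrected here in one place.
ATOM_TRANSITIONS: dict[str, dict[tuple[str, int], tuple[str | None, int]]] = {
    "PDH": {
        ("pyruvate", 1): (None, 1),
        ("pyruvate", 2): ("acetyl", 1),
        ("pyruvate", 3): ("acetyl", 2),
    },
    "PC": {
        ("pyruvate", 1): ("oaa", 1),
        ("pyruvate", 2): ("oaa", 2),
        ("pyruvate", 3): ("oaa", 3),
        ("co2", 1): ("oaa", 4),
    },
    # citrate synthase -> isocitrate dehydrogenase -> aKG, condensed
    "CS_IDH": {
        ("oaa", 1): (None, 1),
        ("oaa", 2): ("akg", 3),
        ("oaa", 3): ("akg", 2),
        ("oaa", 4): ("akg", 1),
        ("acetyl", 1): ("akg", 5),
        ("acetyl", 2): ("akg", 4),
    },
    "AKGDH": {
        ("akg", 1): (None, 1),
        ("akg", 2): ("succinate", 1),
        ("akg", 3): ("succinate", 2),
        ("akg", 4): ("succinate", 3),
        ("akg", 5): ("succinate", 4),
    },
    "PEPCK": {
        ("oaa", 1): ("pep", 1),
        ("oaa", 2): ("pep", 2),
        ("oaa", 3): ("pep", 3),
        ("oaa", 4): (None, 1),
    },
}

#: Symmetric succinate/fumarate step: positions exchanged 50/50.
SCRAMBLE_PAIRS: tuple[tuple[int, int], ...] = ((1, 4), (2, 3))

_POOL_SIZES = {"pyruvate": 3, "acetyl": 2, "oaa": 4, "akg": 5,
               "pep": 3, "triose": 3, "succinate": 4, "co2": 1}


@dataclass(frozen=True)
class FluxParams:
    """True flux configuration of a simulated (or fitted) study.

    Parameters
    ----------
    v_cs : citrate synthase flux, umol/(kg min) (or per-g-liver units).
    r_pc : V_PC / V_CS anaplerotic ratio, >= 0.
    r_pdh : V_PDH / V_CS, fraction of TCA oxidation fed by glucose-derived
        pyruvate, in [0, 1]; the remainder (1 - r_pdh) is fatty-acid /
        other acetyl-CoA sources.
    v_egp : endogenous glucose production, same flux units.
    f_pc : fraction of gluconeogenesis from pyruvate (V_PEPCK / V_GNG).
    v_pk : pyruvate-kinase back-flux; default 0 (< 10 % of V_PC in vivo,
        neglected by the inference equations).
    x_lac : fractional 13C enrichment delivered to pyruvate C3 by the
        [3-13C]lactate tracer, after dilution by unlabeled influx.
    x_co2 : fractional bicarbonate enrichment (default 0).
    """

    v_cs: float = 100.0
    r_pc: float = 2.0
    r_pdh: float = 0.25
    v_egp: float = 100.0
    f_pc: float = 0.9
    v_pk: float = 0.0
    x_lac: float = 0.12
    x_co2: float = 0.0

    def __post_init__(self) -> None:
        if self.v_cs < 0 or self.v_egp < 0 or self.v_pk < 0:
            raise ValueError("fluxes must be non-negative")
        if self.r_pc < 0:
            raise ValueError(f"r_pc must be >= 0, got {self.r_pc}")
        if not 0.0 <= self.r_pdh <= 1.0:
            raise ValueError(f"r_pdh must lie in [0, 1], got {self.r_pdh}")
        if not 0.0 <= self.f_pc <= 1.0:
            raise ValueError(f"f_pc must lie in [0, 1], got {self.f_pc}")
        if not 0.0 <= self.x_lac <= 1.0 or not 0.0 <= self.x_co2 <= 1.0:
            raise ValueError("enrichments are fractional, in [0, 1]")


@dataclass
class PositionalState:
    """Per-carbon fractional enrichments of every modelled pool."""

    pyruvate: np.ndarray   # C1..C3
    acetyl: np.ndarray     # C1..C2
    oaa: np.ndarray        # oxaloacetate/malate C1..C4
    akg: np.ndarray        # alpha-KG/glutamate C1..C5
    pep: np.ndarray        # C1..C3
    triose: np.ndarray     # C1..C3

    def as_dict(self) -> dict[str, np.ndarray]:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}


_OBSERVABLES = (
    "alanine_c3",
    "malate_total", "malate_c123",
    "glutamate_total", "glutamate_c45",
    "glucose_m1", "glucose_m2",
    "glucose_f456_m1", "glucose_f456_m2",
    "glucose_m7h", "palmitate_m16",
)


@dataclass
class EnrichmentSet:
    """Observable enrichments of one sample (fractional, background-corrected).

    ``glucose_m*`` are whole-molecule 13C mass isotopomer fractions of
    plasma/media glucose; ``glucose_f456_m*`` the same for the carbons
    4-6 fragment (one gluconeogenic triose).  ``glucose_m7h`` and
    ``palmitate_m16`` are the plasma tracer enrichments of the [2H7]
    glucose and [U-13C16] palmitate infusions, present only for in vivo
    studies.
    """

    alanine_c3: float = 0.0
    malate_total: float = 0.0
    malate_c123: float = 0.0
    glutamate_total: float = 0.0
    glutamate_c45: float = 0.0
    glucose_m1: float = 0.0
    glucose_m2: float = 0.0
    glucose_f456_m1: float = 0.0
    glucose_f456_m2: float = 0.0
    glucose_m7h: float | None = None
    palmitate_m16: float | None = None

    def as_dict(self) -> dict[str, float]:
        out = {}
        for name in _OBSERVABLES:
            v = getattr(self, name)
            if v is not None:
                out[name] = float(v)
        return out


def _apply(reaction: str, pools: dict[str, np.ndarray],
           out_pool: str) -> np.ndarray:
    """Propagate enrichments through one reaction of the transition table."""
    size = _POOL_SIZES[out_pool]
    out = np.zeros(size)
    for (src, s_pos), (dst, d_pos) in ATOM_TRANSITIONS[reaction].items():
        if dst == out_pool:
            out[d_pos - 1] = pools[src][s_pos - 1]
    return out


def _scramble(vec: np.ndarray) -> np.ndarray:
    """Symmetric (fumarate) step: average exchanged carbon pairs."""
    out = vec.astype(float).copy()
    for i, j in SCRAMBLE_PAIRS:
        m = 0.5 * (vec[i - 1] + vec[j - 1])
        out[i - 1] = out[j - 1] = m
    return out


def _downstream(oaa: np.ndarray, params: FluxParams) -> dict[str, np.ndarray]:
    """One pass of the cycle: pools implied by a given OAA/malate enrichment."""
    pools: dict[str, np.ndarray] = {
        "pyruvate": np.array([0.0, 0.0, params.x_lac]),
        "co2": np.array([params.x_co2]),
        "oaa": np.asarray(oaa, dtype=float),
    }
    # acetyl-CoA: fraction r_pdh from PDH, remainder unlabeled (FAO etc.)
    pools["acetyl"] = params.r_pdh * _apply("PDH", pools, "acetyl")
    pools["akg"] = _apply("CS_IDH", pools, "akg")
    pools["succinate"] = _apply("AKGDH", pools, "succinate")
    pools["malate_ret"] = _scramble(pools["succinate"])
    pools["pep"] = _apply("PEPCK", pools, "pep")
    pools["triose"] = pools["pep"].copy()
    return pools


def _oaa_update(oaa: np.ndarray, params: FluxParams) -> np.ndarray:
    """Flux-weighted OAA/malate balance: PC inflow plus cycle return.

    The pool receives V_PC from pyruvate carboxylation and V_CS from the
    returning cycle carbon (malate), and loses V_CS + V_PEPCK; at steady
    state inflow composition sets the pool enrichment.
    """
    pools = _downstream(oaa, params)
    pc_oaa = _apply("PC", {"pyruvate": pools["pyruvate"],
                           "co2": pools["co2"]}, "oaa")
    r = params.r_pc
    return (r * pc_oaa + pools["malate_ret"]) / (1.0 + r)


def steady_state(params: FluxParams, method: str = "direct",
                 tol: float = 1e-12, max_iter: int = 100_000) -> PositionalState:
    """Solve the positional-enrichment balance at isotopic steady state.

    The OAA/malate update is affine in the OAA enrichment vector at fixed
    flux ratios, so ``method="direct"`` builds the 4x4 linear map by
    probing and solves it exactly.  ``method="iterate"`` runs fixed-point
    iteration to a residual below ``tol`` and is kept as an independent
    cross-check of the direct solve.
    """
    if params.v_cs <= 0 and params.r_pdh > 0:
        raise ValueError("v_cs must be > 0 for an active TCA cycle")
    if method == "direct":
        b = _oaa_update(np.zeros(4), params)
        a_mat = np.empty((4, 4))
        for i in range(4):
            e = np.zeros(4)
            e[i] = 1.0
            a_mat[:, i] = _oaa_update(e, params) - b
        oaa = np.linalg.solve(np.eye(4) - a_mat, b)
    elif method == "iterate":
        oaa = np.zeros(4)
        for _ in range(max_iter):
            new = _oaa_update(oaa, params)
            resid = float(np.max(np.abs(new - oaa)))
            oaa = new
            if resid < tol:
                break
        else:
            raise RuntimeError(
                f"fixed-point iteration did not converge; residual {resid:.3e}")
    else:
        raise ValueError(f"unknown method {method!r}")

    pools = _downstream(oaa, params)
    return PositionalState(
        pyruvate=pools["pyruvate"],
        acetyl=pools["acetyl"],
        oaa=oaa,
        akg=pools["akg"],
        pep=pools["pep"],
        triose=pools["triose"],
    )


def _mid_from_positions(enrich: np.ndarray) -> np.ndarray:
    """Mass isotopomer distribution of a molecule with independent positions."""
    mid = np.array([1.0])
    for q in enrich:
        mid = np.convolve(mid, [1.0 - q, q])
    return mid


def observe(state: PositionalState, params: FluxParams) -> EnrichmentSet:
    """Fragment observables implied by a positional state.

    Glucose mass isotopomers are assembled from two trioses drawn
    independently from the triose pool; the whole-molecule pattern is
    mixed with the unlabeled glucose fraction 1 - f_pc (glucose not made
    from pyruvate-derived trioses).
    """
    m = state.oaa
    g = state.akg
    triose_mid = _mid_from_positions(state.triose)
    glucose_mid = np.convolve(triose_mid, triose_mid)
    f = params.f_pc
    return EnrichmentSet(
        alanine_c3=float(state.pyruvate[2]),
        malate_total=float(m.sum()),
        malate_c123=float(m[:3].sum()),
        glutamate_total=float(g.sum()),
        glutamate_c45=float(g[3] + g[4]),
        glucose_m1=float(f * glucose_mid[1]),
        glucose_m2=float(f * glucose_mid[2]),
        glucose_f456_m1=float(f * triose_mid[1]),
        glucose_f456_m2=float(f * triose_mid[2]),
    )


def add_noise(obs: EnrichmentSet, cv: float, seed: int | np.random.Generator,
              ) -> EnrichmentSet:
    """Multiplicative, mean-preserving log-normal noise per observable.

    ``cv`` is the coefficient of variation of the noise factor; the
    log-normal sigma is sqrt(ln(1 + cv^2)) so the empirical CV matches
    the nominal one.  ``cv = 0`` returns the input unchanged.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if cv == 0:
        return replace(obs)
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv * cv))
    kwargs: dict[str, float] = {}
    for name in _OBSERVABLES:
        v = getattr(obs, name)
        if v is None:
            continue
        factor = rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma)
        kwargs[name] = max(0.0, float(v) * factor)
    return EnrichmentSet(**{**{k: None for k in ("glucose_m7h", "palmitate_m16")},
                            **kwargs})


def _fit_residuals(theta: np.ndarray, obs: EnrichmentSet) -> np.ndarray:
    r_pc, r_pdh, f_pc, x_lac = theta
    params = FluxParams(r_pc=r_pc, r_pdh=min(max(r_pdh, 0.0), 1.0),
                        f_pc=min(max(f_pc, 0.0), 1.0), x_lac=x_lac)
    model = observe(steady_state(params), params).as_dict()
    target = obs.as_dict()
    keys = [k for k in model if k in target]
    # relative residuals: observables span orders of magnitude and carry
    # multiplicative noise, so equal relative weight conditions the fit
    return np.array([(model[k] - target[k]) / max(abs(target[k]), 1e-4)
                     for k in keys])


def invert_numerically(obs: EnrichmentSet,
                       init: FluxParams | None = None) -> FluxParams:
    """Least-squares inversion of the forward model (oracle estimator).

    Fits (r_pc, r_pdh, f_pc, x_lac) by minimising squared residuals
    between modelled and observed enrichments.  Intended for noiseless or
    near-noiseless data, as an independent check of the closed-form
    estimation equations.
    """
    from scipy.optimize import least_squares

    target = obs.as_dict()
    scale = max(abs(v) for v in target.values()) if target else 0.0
    if scale <= 0:
        raise ValueError("all observables are zero; fluxes not identifiable")
    init = init or FluxParams(r_pc=1.0, r_pdh=0.3, f_pc=0.8, x_lac=0.1)
    theta0 = np.array([init.r_pc, init.r_pdh, init.f_pc, init.x_lac])
    res = least_squares(
        _fit_residuals, theta0, args=(obs,),
        bounds=([0.0, 0.0, 0.0, 0.0], [np.inf, 1.0, 1.0, 1.0]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not res.success:
        raise RuntimeError(f"inversion failed: {res.message}")
    r_pc, r_pdh, f_pc, x_lac = res.x
    return FluxParams(r_pc=float(r_pc), r_pdh=float(r_pdh),
                      f_pc=float(f_pc), x_lac=float(x_lac))


class TracerModel:
    """Forward tracer model bound to one flux configuration.

    A thin object layer over :func:`steady_state`, :func:`observe` and
    :func:`add_noise` so simulation reads naturally::

        obs = TracerModel(FluxParams(r_pc=2.0)).simulate(cv=0.05, seed=7)
    """

    def __init__(self, params: FluxParams):
        self.params = params

    def steady_state(self, method: str = "direct") -> PositionalState:
        return steady_state(self.params, method=method)

    def observe(self, state: PositionalState | None = None) -> EnrichmentSet:
        state = state if state is not None else self.steady_state()
        return observe(state, self.params)

    def simulate(self, cv: float = 0.0,
                 seed: int | np.random.Generator = 0) -> EnrichmentSet:
        return add_noise(self.observe(), cv, seed)
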