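"""Synthetic-trial generator: seven data-generating scenarios.

Each scenario draws candidate biomarkers, assigns the arm by a fair coin
(1:1 randomisation, pi = 1/2) and computes BOTH potential outcomes from

    Y(a) = prognostic(V) + a * effect(V) + e,        a in {-1/2, +1/2}

with a single error draw e per subject, so the individual treatment effect
tau = Y(+1/2) - Y(-1/2) = effect(V) is free of noise and the optimal arm is
known exactly: treat iff tau > 0.  The observed outcome is the potential
outcome selected by the realised arm.

Scenario roster (coefficients are part of the registry and auditable via
:func:`scenario_table`):

- ``1a`` simple linear; ``1b`` the same with exchangeable correlation 0.5
  among the biomarkers; ``2`` weak moderators; ``3`` a strong *unobserved*
  prognostic variable U1; ``4`` a strong unobserved moderator U2; ``5`` a
  misspecified prognostic part (squares/products, U1 hidden, M1 observed);
  ``6`` a misspecified moderator part (interactions, U2 hidden); ``7`` a
  non-linear model whose treatment effect is a ratio of linear forms.

Distributional defaults (the source publication leaves them unstated; they
are package choices, configurable per spec):

- continuous variables X1, Z1, Z2, U1, U2, M1 iid standard normal;
- Z3 categorical with three equally likely levels, generated by cutting a
  standard-normal latent at its tertiles and reference-coded as indicators
  Z3.lv2, Z3.lv3 (reference lv1);
- error e ~ Normal(0, sigma_e), sigma_e = 1;
- scenario 1b: exchangeable correlation rho = 0.5 over the (X1, Z1, Z2,
  Z3-latent) block, so with rho = 0 scenario 1b is draw-for-draw identical
  to 1a.

The generated trial exposes only the scenario's observed variables (e.g.
scenario 3 hides U1); all latent variables, potential outcomes, tau and the
optimal arm travel alongside as hidden oracle columns.  Every observed
variable is declared with role ``both``: an analyst without knowledge of the
generating process lets all observed variables enter both the prognostic and
the moderator part of each prediction model, which is also what makes the
prognostic score (fitted on controls) capture the full treatment-free
variation available to the matched method.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .trial import ROLE_BOTH, TrialData

Term = tuple[float, tuple[str, ...]]

#: draw order of the standard-normal latents; the first four form the
#: correlated block in scenario 1b ("_Z3" is the latent cut into Z3 levels).
_LATENT_ORDER = ("X1", "Z1", "Z2", "_Z3", "U1", "U2", "M1")
_CORRELATED = 4
_TERTILES = stats.norm.ppf([1.0 / 3.0, 2.0 / 3.0])


@dataclasses.dataclass(frozen=True)
class ScenarioSpec:
    """One data-generating process: term lists, observed set, noise level."""

    scenario_id: str
    label: str
    prognostic_terms: tuple[Term, ...]
    moderator_terms: tuple[Term, ...]
    observed: tuple[str, ...]
    moderator_denominator: tuple[Term, ...] | None = None
    rho: float = 0.0
    sigma_e: float = 1.0


_BASE_PROG: tuple[Term, ...] = (
    (3.0, ("X1",)), (2.0, ("Z1",)), (-0.5, ("Z3.lv2",)), (-1.5, ("Z3.lv3",)))
_BASE_MOD: tuple[Term, ...] = (
    (2.0, ()), (2.0, ("Z1",)), (-1.5, ("Z2",)), (-3.0, ("Z3.lv3",)))
_OBS_BASE = ("X1", "Z1", "Z2", "Z3.lv2", "Z3.lv3")

SCENARIOS: dict[str, ScenarioSpec] = {
    "1a": ScenarioSpec("1a", "Simple linear", _BASE_PROG, _BASE_MOD, _OBS_BASE),
    "1b": ScenarioSpec("1b", "Simple linear with correlated biomarkers",
                       _BASE_PROG, _BASE_MOD, _OBS_BASE, rho=0.5),
    "2": ScenarioSpec("2", "Linear with weak moderators", _BASE_PROG,
                      ((2.0, ()), (0.5, ("Z1",)), (-0.5, ("Z2",)),
                       (-0.25, ("Z3.lv3",))), _OBS_BASE),
    "3": ScenarioSpec("3", "Strong unobserved prognostic marker",
                      ((12.0, ("U1",)),) + _BASE_PROG, _BASE_MOD, _OBS_BASE),
    "4": ScenarioSpec("4", "Strong unobserved moderator variables", _BASE_PROG,
                      ((2.0, ()), (10.0, ("U2",)), (2.0, ("Z1",)),
                       (-1.5, ("Z2",)), (-3.0, ("Z3.lv3",))), _OBS_BASE),
    "5": ScenarioSpec("5", "Misspecified prognostic part",
                      _BASE_PROG + ((2.0, ("X1", "X1")), (1.5, ("U1", "X1")),
                                    (-1.5, ("X1", "M1")),
                                    (0.5, ("X1", "Z1", "Z3.lv3"))),
                      _BASE_MOD,
                      ("X1", "M1", "Z1", "Z2", "Z3.lv2", "Z3.lv3")),
    "6": ScenarioSpec("6", "Misspecified moderator part", _BASE_PROG,
                      _BASE_MOD + ((2.0, ("Z1", "Z2")),
                                   (-1.5, ("Z1", "Z2", "U2")),
                                   (0.5, ("Z1", "Z2", "Z3.lv2"))), _OBS_BASE),
    "7": ScenarioSpec("7", "Non-linear model", _BASE_PROG, _BASE_MOD, _OBS_BASE,
                      moderator_denominator=((-2.0, ("Z1",)), (1.5, ("Z2",)),
                                             (-1.5, ("Z3.lv3",)))),
}


def get_scenario(scenario_id: str, sigma_e: float | None = None,
                 rho: float | None = None) -> ScenarioSpec:
    """Look up a scenario, optionally overriding the noise SD / correlation."""
    key = str(scenario_id)
    if key not in SCENARIOS:
        raise KeyError(f"unknown scenario {scenario_id!r}; "
                       f"known: {sorted(SCENARIOS)}")
    spec = SCENARIOS[key]
    changes = {}
    if sigma_e is not None:
        changes["sigma_e"] = float(sigma_e)
    if rho is not None:
        changes["rho"] = float(rho)
    return dataclasses.replace(spec, **changes) if changes else spec


def _term_str(coef: float, factors: tuple[str, ...]) -> str:
    head = f"{coef:g}"
    return head if not factors else head + "*" + "*".join(factors)


def scenario_table() -> dict:
    """Human-readable registry (scenario id -> terms/observed) for audit."""
    out = {}
    for key, s in SCENARIOS.items():
        entry = {
            "label": s.label,
            "prognostic": [_term_str(c, f) for c, f in s.prognostic_terms],
            "moderator": [_term_str(c, f) for c, f in s.moderator_terms],
            "observed": list(s.observed),
            "sigma_e": s.sigma_e,
            "rho": s.rho,
        }
        if s.moderator_denominator is not None:
            entry["moderator_denominator"] = [
                _term_str(c, f) for c, f in s.moderator_denominator]
        out[key] = entry
    return out


def scenario_config_yaml() -> str:
    return yaml.safe_dump(scenario_table(), sort_keys=False)


# ---------------------------------------------------------------------------
# Drawing
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SimulatedTrial:
    """A drawn trial with its oracle columns.

    ``data`` is the observed-variable :class:`TrialData`; ``hidden`` holds
    every variable (latent included); ``y_treated``/``y_control`` are the
    potential outcomes, ``tau`` their difference, ``optimal`` the optimal
    arm in +/-1/2 coding.
    """

    data: TrialData
    hidden: pd.DataFrame
    y_treated: np.ndarray
    y_control: np.ndarray
    tau: np.ndarray
    optimal: np.ndarray
    n_redrawn: int = 0


def _chol(rho: float) -> np.ndarray:
    corr = np.full((_CORRELATED, _CORRELATED), rho)
    np.fill_diagonal(corr, 1.0)
    return np.linalg.cholesky(corr)


def _draw_biomarkers(rng: np.random.Generator, m: int,
                     chol: np.ndarray) -> dict[str, np.ndarray]:
    lat = rng.standard_normal((m, len(_LATENT_ORDER)))
    lat[:, :_CORRELATED] = lat[:, :_CORRELATED] @ chol.T
    table = {name: lat[:, j].copy() for j, name in enumerate(_LATENT_ORDER)}
    z3 = table.pop("_Z3")
    table["Z3.lv2"] = ((z3 >= _TERTILES[0]) & (z3 < _TERTILES[1])).astype(float)
    table["Z3.lv3"] = (z3 >= _TERTILES[1]).astype(float)
    return table


def _eval_terms(terms: tuple[Term, ...], table: dict[str, np.ndarray],
                m: int) -> np.ndarray:
    out = np.zeros(m)
    for coef, factors in terms:
        v = np.full(m, coef)
        for f in factors:
            v = v * table[f]
        out += v
    return out


def draw_trial(spec: ScenarioSpec, n: int, seed) -> SimulatedTrial:
    """Draw one trial of size n; deterministic given (spec, n, seed).

    ``seed`` may be an int, a ``numpy.random.SeedSequence`` or a Generator.
    For the ratio-effect scenario, subjects whose denominator is exactly zero
    have their biomarkers redrawn (counted in ``n_redrawn``).
    """
    if n < 4:
        raise ValueError("n must be at least 4")
    rng = np.random.default_rng(seed)
    chol = _chol(spec.rho)
    table = _draw_biomarkers(rng, n, chol)
    n_redrawn = 0
    if spec.moderator_denominator is not None:
        while True:
            denom = _eval_terms(spec.moderator_denominator, table, n)
            bad = np.flatnonzero(denom == 0.0)
            if bad.size == 0:
                break
            n_redrawn += bad.size
            fresh = _draw_biomarkers(rng, bad.size, chol)
            for name in table:
                table[name][bad] = fresh[name]
    A = np.where(rng.random(n) < 0.5, 0.5, -0.5)
    e = spec.sigma_e * rng.standard_normal(n)
    prog = _eval_terms(spec.prognostic_terms, table, n)
    effect = _eval_terms(spec.moderator_terms, table, n)
    if spec.moderator_denominator is not None:
        effect = effect / _eval_terms(spec.moderator_denominator, table, n)
    y_treated = prog + 0.5 * effect + e
    y_control = prog - 0.5 * effect + e
    Y = np.where(A > 0, y_treated, y_control)
    tau = effect
    optimal = np.where(tau > 0, 0.5, -0.5)

    roles = {name: ROLE_BOTH for name in spec.observed}
    data = TrialData(
        subject_id=tuple(f"S{i + 1}" for i in range(n)),
        Y=Y,
        A=A,
        biomarkers=pd.DataFrame({name: table[name] for name in spec.observed}),
        roles=roles,
        pi=0.5,
    )
    hidden = pd.DataFrame({name: table[name] for name in table})
    hidden["y_treated"] = y_treated
    hidden["y_control"] = y_control
    hidden["tau"] = tau
    hidden["optimal"] = optimal
    return SimulatedTrial(data=data, hidden=hidden, y_treated=y_treated,
                          y_control=y_control, tau=tau, optimal=optimal,
                          n_redrawn=n_redrawn)


def make_train_test(spec: ScenarioSpec, n: int,
                    seed: int) -> tuple[SimulatedTrial, SimulatedTrial]:
    """Two independent draws of size n from one master seed.

    Train and test use the disjoint sub-streams SeedSequence([seed, 0]) and
    SeedSequence([seed, 1]), so they share no random numbers and either can
    be regenerated from the master seed alone.
    """
    train = draw_trial(spec, n, np.random.SeedSequence([int(seed), 0]))
    test = draw_trial(spec, n, np.random.SeedSequence([int(seed), 1]))
    return train, test


def write_simulated(sim: SimulatedTrial, path) -> None:
    """Write the observed trial (CSV + schema sidecar) and the hidden oracle
    columns to ``<path>.hidden.csv``."""
    from pathlib import Path

    from .trial import write_trial

    path = Path(path)
    write_trial(sim.data, path)
    hidden = sim.hidden.copy()
    hidden.insert(0, "subject_id", list(sim.data.subject_id))
    hidden.to_csv(path.with_name(path.name + ".hidden.csv"), index=False)
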