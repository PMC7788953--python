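"""Estimators for personalised treatment recommendations (PTRs).

Three parametric routes from a two-arm trial to a linear treatment rule:

1. **Regression with interactions** — OLS of the outcome on prognostic and
   moderator main effects, the effect-coded arm A, and A-by-moderator
   interactions.  With ``Y = a0 + a·X + A (b0 + b·Z) + e`` the optimal rule
   recommends treatment when ``b0 + b·Z > 0``.

2. **Kraemer's composite moderator** — form every treated-by-control pair;
   within a pair the outcome difference decomposes as
   ``D(Y) = a·D(X) + b0 + b·m(Z) + D(e)`` where ``D`` is the within-pair
   difference and ``m`` the within-pair mean.  Regressing D(Y) on the pair
   means m(Z_k) of all K candidate moderators yields weights w_k; the
   composite moderator is ``Z* = sum_k w_k Z_k`` and the rule comes from a
   second regression of Y on [1, Z*, A, A·Z*].

3. **Prognostic-score-matched (modified Kraemer)** — instead of all pairs,
   fit a prognostic model on controls only (moderators excluded), score every
   subject with its predicted treatment-free outcome, and pair each treated
   subject with its single nearest control by score (with replacement),
   subject to a caliper of 0.1 score standard deviations.  Treated subjects
   without an admissible match are dropped.  Weights, composite and rule are
   then computed exactly as in Kraemer's method, on the matched pairs.

The pairwise decomposition motivates the matching: pairing subjects with
similar treatment-free prognosis shrinks the ``a·D(X)`` nuisance term in
D(Y), so the weight regression sees a cleaner moderator signal.

A two-stage moderator screening procedure (univariate interaction p < 0.10,
then joint model with exclusion at p > 0.3) is provided for applications
where the candidate set must be reduced before fitting a rule.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm

from .errors import (
    DataError,
    DegenerateCompositeError,
    DegenerateScoreError,
    InsufficientDataError,
    NoPairsError,
    SchemaError,
    SingularFitError,
)
from .trial import TrialData

RECOMMEND_TREAT = 0.5
RECOMMEND_CONTROL = -0.5


# ---------------------------------------------------------------------------
# Shared OLS helper with an explicit rank check
# ---------------------------------------------------------------------------

def _ols(design: np.ndarray, y: np.ndarray, columns: list[str]) -> np.ndarray:
    """Least-squares coefficients; raises SingularFitError naming the
    linearly dependent columns when the design is rank deficient."""
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        _, r, pivot = scipy.linalg.qr(design, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = max(design.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
        dependent = [columns[j] for j in pivot[np.flatnonzero(diag <= tol)]]
        dependent += [columns[j] for j in pivot[len(diag):]]
        raise SingularFitError(
            f"design matrix is rank deficient (rank {rank} < {design.shape[1]}); "
            f"collinear columns: {dependent}", columns=tuple(dependent))
    return coef


def _require_both_arms(data: TrialData, what: str) -> None:
    if data.n_treated == 0 or data.n_control == 0:
        raise NoPairsError(f"{what} requires at least one subject in each arm "
                           f"(treated={data.n_treated}, control={data.n_control})")


# ---------------------------------------------------------------------------
# Treatment rules
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PTRRule:
    """A linear personalised treatment recommendation.

    ``recommend`` returns +1/2 (treat) iff the linear score
    ``intercept + sum_k coef_k * value_k`` is strictly positive, and -1/2
    (control) otherwise; an exact tie at zero recommends control.

    For ``kind="composite"`` the single coefficient is over the composite
    moderator Z* and ``weights`` stores the moderator weights, so the rule
    expands to an equivalent linear rule over the raw moderators.
    """

    kind: str  # "regression" | "composite"
    intercept: float
    coefficients: dict[str, float]
    weights: dict[str, float] | None = None
    diagnostics: dict = dataclasses.field(default_factory=dict)

    def expanded_coefficients(self) -> dict[str, float]:
        """Coefficients over raw moderators (expands a composite rule)."""
        if self.kind == "composite":
            beta_star = self.coefficients["Z*"]
            return {k: beta_star * w for k, w in (self.weights or {}).items()}
        return dict(self.coefficients)

    def decision_values(self, data) -> np.ndarray:
        """Linear score per subject; ``data`` is a TrialData or DataFrame."""
        bio = data.biomarkers if isinstance(data, TrialData) else data
        coefs = self.expanded_coefficients()
        missing = [k for k in coefs if k not in bio.columns]
        if missing:
            raise SchemaError(f"rule references biomarkers absent from data: {missing}")
        vals = np.full(len(bio), float(self.intercept))
        for name, c in coefs.items():
            vals = vals + c * bio[name].to_numpy(dtype=float)
        return vals

    def recommend(self, data) -> np.ndarray:
        """Per-subject recommendation in {-1/2, +1/2} (strict > 0 treats)."""
        return np.where(self.decision_values(data) > 0,
                        RECOMMEND_TREAT, RECOMMEND_CONTROL)

    def __str__(self) -> str:
        coefs = self.expanded_coefficients()
        terms = "".join(f" {c:+.3f}*{k}" for k, c in coefs.items())
        return f"I{{{self.intercept:.3f}{terms} > 0}}"


def save_rule(rule: PTRRule, path) -> None:
    """Serialise a rule to a plain-text ``name=value`` coefficient file."""
    lines = [f"kind={rule.kind}", f"intercept={rule.intercept!r}"]
    lines += [f"coef.{k}={v!r}" for k, v in rule.coefficients.items()]
    if rule.weights is not None:
        lines += [f"weight.{k}={v!r}" for k, v in rule.weights.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def load_rule(path) -> PTRRule:
    """Read a rule written by :func:`save_rule`."""
    kind, intercept = "regression", 0.0
    coefficients: dict[str, float] = {}
    weights: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        if key == "kind":
            kind = value
        elif key == "intercept":
            intercept = float(value)
        elif key.startswith("coef."):
            coefficients[key[5:]] = float(value)
        elif key.startswith("weight."):
            weights[key[7:]] = float(value)
        else:
            raise SchemaError(f"unrecognised rule-file line: {line!r}")
    return PTRRule(kind=kind, intercept=intercept, coefficients=coefficients,
                   weights=weights or None)


# ---------------------------------------------------------------------------
# Method 1: regression with treatment-by-moderator interactions
# ---------------------------------------------------------------------------

def _main_effect_names(data: TrialData) -> list[str]:
    """Prognostic then remaining moderator main effects, each once."""
    names = list(data.prognostic_names)
    names += [z for z in data.moderator_names if z not in names]
    return names


def fit_regression_ptr(data: TrialData) -> PTRRule:
    """OLS of Y on [1, main effects, A, A x moderators]; the rule's intercept
    is the A coefficient and its coefficients are the interaction slopes."""
    _require_both_arms(data, "fit_regression_ptr")
    mains = _main_effect_names(data)
    mods = data.moderator_names
    if not mods:
        raise SchemaError("no candidate moderators declared")
    bio = data.biomarkers
    cols = ["const"] + mains + ["A"] + [f"A:{z}" for z in mods]
    if data.n <= len(cols):
        raise InsufficientDataError(
            f"n={data.n} subjects for {len(cols)} parameters")
    design = np.column_stack(
        [np.ones(data.n)]
        + [bio[m].to_numpy(float) for m in mains]
        + [data.A]
        + [data.A * bio[z].to_numpy(float) for z in mods])
    coef = _ols(design, data.Y, cols)
    lookup = dict(zip(cols, coef))
    return PTRRule(
        kind="regression",
        intercept=float(lookup["A"]),
        coefficients={z: float(lookup[f"A:{z}"]) for z in mods},
        diagnostics={"main_effects": {m: float(lookup[m]) for m in mains},
                     "const": float(lookup["const"])},
    )


# ---------------------------------------------------------------------------
# Pairwise machinery (Kraemer)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PairSet:
    """Treated-by-control pair rows.

    ``dY`` holds the within-pair outcome differences Y_T - Y_C, ``muZ`` the
    within-pair means of each candidate moderator, ``dX`` the within-pair
    differences of each prognostic variable.  ``provenance`` is ``all_pairs``
    (the full treated x control product) or ``matched`` (one nearest-neighbour
    match per treated subject; controls may repeat, treated may be dropped).
    """

    treated_id: tuple[str, ...]
    control_id: tuple[str, ...]
    dY: np.ndarray
    muZ: pd.DataFrame
    dX: pd.DataFrame
    provenance: str
    n_excluded: int = 0

    @property
    def n_pairs(self) -> int:
        return len(self.dY)


def _pair_rows(data: TrialData, t_idx: np.ndarray, c_idx: np.ndarray,
               provenance: str, n_excluded: int = 0) -> PairSet:
    bio = data.biomarkers
    mods, progs = data.moderator_names, data.prognostic_names
    muZ = pd.DataFrame({z: (bio[z].to_numpy(float)[t_idx]
                            + bio[z].to_numpy(float)[c_idx]) / 2.0
                        for z in mods})
    dX = pd.DataFrame({x: bio[x].to_numpy(float)[t_idx]
                       - bio[x].to_numpy(float)[c_idx]
                       for x in progs})
    return PairSet(
        treated_id=tuple(data.subject_id[i] for i in t_idx),
        control_id=tuple(data.subject_id[i] for i in c_idx),
        dY=data.Y[t_idx] - data.Y[c_idx],
        muZ=muZ,
        dX=dX,
        provenance=provenance,
        n_excluded=n_excluded,
    )


def build_all_pairs(data: TrialData) -> PairSet:
    """All treated x control combinations (n_T * n_C rows, treated-major)."""
    _require_both_arms(data, "build_all_pairs")
    t = np.flatnonzero(data.treated_mask)
    c = np.flatnonzero(data.control_mask)
    return _pair_rows(data, np.repeat(t, c.size), np.tile(c, t.size), "all_pairs")


@dataclasses.dataclass
class ModeratorWeights:
    """Weights from the pairwise regression D(Y) ~ 1 + m(Z) [+ D(X)].

    ``intercept`` estimates the average treatment effect b0 in the pair
    decomposition; it is reported but does not enter the composite.
    ``prognostic_adjustment`` holds the D(X) coefficients when requested.
    """

    weights: dict[str, float]
    intercept: float
    prognostic_adjustment: dict[str, float] | None = None


def kraemer_weights(pairs: PairSet, adjust_dX: bool = False) -> ModeratorWeights:
    """Joint OLS of the pair outcome differences on the pair moderator means.

    The slope on m(Z_k) is the weight w_k of moderator k.  An intercept is
    always included (the pair decomposition contains the average effect b0).
    With ``adjust_dX`` the prognostic differences D(X) enter as covariates;
    their coefficients are reported separately and never enter the composite.
    """
    mods = list(pairs.muZ.columns)
    progs = list(pairs.dX.columns) if adjust_dX else []
    n_par = 1 + len(mods) + len(progs)
    if pairs.n_pairs < n_par:
        raise InsufficientDataError(
            f"{pairs.n_pairs} pairs for {n_par} weight-regression parameters")
    degenerate = [z for z in mods if np.ptp(pairs.muZ[z].to_numpy(float)) == 0.0]
    if degenerate:
        raise SingularFitError(
            f"pair moderator means with zero variance: {degenerate}",
            columns=tuple(degenerate))
    cols = ["const"] + mods + [f"dX:{x}" for x in progs]
    design = np.column_stack(
        [np.ones(pairs.n_pairs)]
        + [pairs.muZ[z].to_numpy(float) for z in mods]
        + [pairs.dX[x].to_numpy(float) for x in progs])
    coef = _ols(design, pairs.dY, cols)
    lookup = dict(zip(cols, coef))
    return ModeratorWeights(
        weights={z: float(lookup[z]) for z in mods},
        intercept=float(lookup["const"]),
        prognostic_adjustment=(
            {x: float(lookup[f"dX:{x}"]) for x in progs} if adjust_dX else None),
    )


@dataclasses.dataclass
class CompositeModerator:
    """Per-subject composite moderator Z*_i = sum_k w_k Z_ik."""

    weights: dict[str, float]
    values: np.ndarray
    intercept_of_weight_fit: float = 0.0


def composite_values(data: TrialData,
                     weights: ModeratorWeights | Mapping[str, float]) -> CompositeModerator:
    """Evaluate the weighted-sum composite moderator for every subject."""
    if isinstance(weights, ModeratorWeights):
        wmap, intercept = weights.weights, weights.intercept
    else:
        wmap, intercept = dict(weights), 0.0
    unknown = [k for k in wmap if k not in data.biomarkers.columns]
    if unknown:
        raise SchemaError(f"weights reference unknown biomarkers: {unknown}")
    uncovered = [z for z in data.moderator_names if z not in wmap]
    if uncovered:
        raise SchemaError(f"weights missing for candidate moderators: {uncovered}")
    values = np.zeros(data.n)
    for name, w in wmap.items():
        values = values + w * data.biomarkers[name].to_numpy(float)
    return CompositeModerator(weights=dict(wmap), values=values,
                              intercept_of_weight_fit=intercept)


def fit_composite_ptr(data: TrialData, zstar: CompositeModerator) -> PTRRule:
    """OLS of Y on [1, Z*, A, A*Z*]; the rule treats iff b0* + b*·Z* > 0."""
    _require_both_arms(data, "fit_composite_ptr")
    z = np.asarray(zstar.values, dtype=float)
    if np.ptp(z) == 0.0:
        raise DegenerateCompositeError(
            "composite moderator Z* is constant; cannot fit a composite rule",
            diagnostics={"weights": dict(zstar.weights)})
    cols = ["const", "Z*", "A", "A:Z*"]
    design = np.column_stack([np.ones(data.n), z, data.A, data.A * z])
    try:
        coef = _ols(design, data.Y, cols)
    except SingularFitError as err:
        # a numerically constant Z* (weights underflowing to ~0) shows up as
        # collinearity of the Z* columns with the intercept/arm columns
        if {"Z*", "A:Z*"} & set(err.columns):
            raise DegenerateCompositeError(
                "composite moderator Z* is numerically constant; cannot fit "
                "a composite rule",
                diagnostics={"weights": dict(zstar.weights)}) from err
        raise
    lookup = dict(zip(cols, coef))
    return PTRRule(
        kind="composite",
        intercept=float(lookup["A"]),
        coefficients={"Z*": float(lookup["A:Z*"])},
        weights=dict(zstar.weights),
        diagnostics={"alpha0": float(lookup["const"]),
                     "alpha": float(lookup["Z*"])},
    )


def fit_kraemer_ptr(data: TrialData, adjust_dX: bool = False) -> PTRRule:
    """Kraemer's method end-to-end: all pairs -> weights -> composite -> rule."""
    pairs = build_all_pairs(data)
    w = kraemer_weights(pairs, adjust_dX=adjust_dX)
    zstar = composite_values(data, w)
    rule = fit_composite_ptr(data, zstar)
    rule.diagnostics.update(n_pairs=pairs.n_pairs, weights=dict(w.weights),
                            weight_intercept=w.intercept)
    return rule


# ---------------------------------------------------------------------------
# Modified Kraemer: prognostic-score matching
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PrognosticModel:
    """Linear model of the treatment-free outcome, fitted on controls only."""

    intercept: float
    coefficients: dict[str, float]

    def score(self, data) -> np.ndarray:
        """Predicted treatment-free outcome for every subject."""
        bio = data.biomarkers if isinstance(data, TrialData) else data
        missing = [k for k in self.coefficients if k not in bio.columns]
        if missing:
            raise SchemaError(f"prognostic model references absent columns: {missing}")
        s = np.full(len(bio), float(self.intercept))
        for name, c in self.coefficients.items():
            s = s + c * bio[name].to_numpy(float)
        return s


def fit_prognostic_model(data: TrialData) -> PrognosticModel:
    """OLS of Y on the prognostic variables, control-arm rows only.

    Moderator-only variables are excluded by construction.  With no declared
    prognostic variables the model is the control-arm mean.
    """
    ctrl = np.flatnonzero(data.control_mask)
    if ctrl.size == 0:
        raise NoPairsError("no control subjects to fit the prognostic model on")
    progs = data.prognostic_names
    if not progs:
        return PrognosticModel(intercept=float(data.Y[ctrl].mean()), coefficients={})
    if ctrl.size < len(progs) + 1:
        raise InsufficientDataError(
            f"{ctrl.size} controls for {len(progs) + 1} prognostic parameters")
    cols = ["const"] + progs
    design = np.column_stack(
        [np.ones(ctrl.size)]
        + [data.biomarkers[x].to_numpy(float)[ctrl] for x in progs])
    coef = _ols(design, data.Y[ctrl], cols)
    return PrognosticModel(intercept=float(coef[0]),
                           coefficients={x: float(c) for x, c in zip(progs, coef[1:])})


def match_on_prognostic_score(data: TrialData, model: PrognosticModel,
                              caliper_sd: float = 0.1) -> PairSet:
    """Single nearest-neighbour matching on the prognostic score.

    With replacement: each treated subject takes its closest control by
    absolute score distance, provided the distance is within
    ``caliper_sd x SD(score)``; the SD is the sample SD (n-1 denominator)
    over all subjects in both arms.  Equidistant controls are broken by the
    lowest control row index.  Treated subjects with no admissible control
    are dropped and counted in ``n_excluded``.
    """
    if not caliper_sd > 0:
        raise ValueError("caliper_sd must be positive (may be inf)")
    _require_both_arms(data, "match_on_prognostic_score")
    scores = model.score(data)
    sd = float(np.std(scores, ddof=1))
    if sd == 0.0:
        raise DegenerateScoreError("prognostic score is constant across subjects")
    caliper = caliper_sd * sd
    t = np.flatnonzero(data.treated_mask)
    c = np.flatnonzero(data.control_mask)
    dist = np.abs(scores[t][:, None] - scores[c][None, :])
    best = np.argmin(dist, axis=1)  # first occurrence = lowest control index
    dmin = dist[np.arange(t.size), best]
    keep = dmin <= caliper
    n_excluded = int((~keep).sum())
    if not keep.any():
        raise NoPairsError(
            f"no treated subject has a control within the caliper "
            f"({caliper_sd} SD = {caliper:.4g})")
    return _pair_rows(data, t[keep], c[best[keep]], "matched", n_excluded)


def fit_modified_kraemer_ptr(data: TrialData, caliper_sd: float = 0.1,
                             adjust_dX: bool = False) -> PTRRule:
    """Modified Kraemer pipeline: prognostic model on controls, caliper
    matching, pairwise weights on the matched pairs, composite rule."""
    model = fit_prognostic_model(data)
    pairs = match_on_prognostic_score(data, model, caliper_sd=caliper_sd)
    w = kraemer_weights(pairs, adjust_dX=adjust_dX)
    zstar = composite_values(data, w)
    diagnostics = {
        "n_matched": pairs.n_pairs,
        "n_excluded": pairs.n_excluded,
        "weights": dict(w.weights),
        "weight_intercept": w.intercept,
        "prognostic_model": {"intercept": model.intercept,
                             "coefficients": dict(model.coefficients)},
    }
    try:
        rule = fit_composite_ptr(data, zstar)
    except DegenerateCompositeError as err:
        err.diagnostics.update(diagnostics)
        raise
    rule.diagnostics.update(diagnostics)
    return rule


# ---------------------------------------------------------------------------
# Moderator screening (two-stage, as used in trial applications)
# ---------------------------------------------------------------------------

def moderator_interaction_pvalues(data: TrialData) -> dict[str, float]:
    """Univariate Wald p-value of the A x Z_k interaction per candidate.

    Each candidate is tested in its own OLS model
    ``Y ~ 1 + prognostic variables + Z_k + A + A*Z_k``.
    """
    out: dict[str, float] = {}
    y = data.Y
    bio = data.biomarkers
    progs = data.prognostic_names
    for z in data.moderator_names:
        mains = progs + ([z] if z not in progs else [])
        design = pd.DataFrame({"const": np.ones(data.n)})
        for m in mains:
            design[m] = bio[m].to_numpy(float)
        design["A"] = data.A
        design[f"A:{z}"] = data.A * bio[z].to_numpy(float)
        res = sm.OLS(y, design).fit()
        out[z] = float(res.pvalues[f"A:{z}"])
    return out


def screen_moderators(data: TrialData, p_uni: float = 0.10,
                      p_multi: float = 0.30) -> list[str]:
    """Two-stage moderator screening.

    Stage 1 keeps candidates whose univariate interaction p-value is below
    ``p_uni``; stage 2 refits one joint model with all retained moderators
    (main effects and interactions) and drops those with interaction p-value
    above ``p_multi``.  Returns the survivors in column order; an empty list
    is a legitimate outcome, not an error.
    """
    stage1 = moderator_interaction_pvalues(data)
    retained = [z for z in data.moderator_names if stage1[z] < p_uni]
    if not retained:
        return []
    bio = data.biomarkers
    mains = data.prognostic_names + [z for z in retained
                                     if z not in data.prognostic_names]
    design = pd.DataFrame({"const": np.ones(data.n)})
    for m in mains:
        design[m] = bio[m].to_numpy(float)
    design["A"] = data.A
    for z in retained:
        design[f"A:{z}"] = data.A * bio[z].to_numpy(float)
    res = sm.OLS(data.Y, design).fit()
    return [z for z in retained if float(res.pvalues[f"A:{z}"]) <= p_multi]
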