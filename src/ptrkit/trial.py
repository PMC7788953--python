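"""Subject-level trial data model and delimited-file I/O.

A two-arm randomised trial is held as a :class:`TrialData`: a continuous
outcome ``Y`` (higher is better), an effect-coded arm ``A`` (+1/2 treated,
-1/2 control), a numeric biomarker matrix, a role declaration per biomarker
(``prognostic``, ``moderator`` or ``both``) and the randomisation probability
``pi`` of assignment to the treated arm.

Effect coding is normalised on the way in: files may code the arm 0/1 or
+/-1/2 and are recoded to +/-1/2, which makes the indicator products in the
inverse-probability-weighted value estimator literal arithmetic.

Categorical biomarkers are expanded to reference-coded indicator columns
(``Z3.lv2``, ``Z3.lv3`` against a reference level) at read time; levels are
ordered lexicographically and the first level is the reference unless the
schema overrides it.

Missing values in the outcome, arm or biomarkers are rejected, never imputed.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import CodingError, DataError, SchemaError

ROLE_PROGNOSTIC = "prognostic"
ROLE_MODERATOR = "moderator"
ROLE_BOTH = "both"
VALID_ROLES = frozenset({ROLE_PROGNOSTIC, ROLE_MODERATOR, ROLE_BOTH})

TREATED = 0.5
CONTROL = -0.5


@dataclasses.dataclass(frozen=True)
class TrialData:
    """Validated subject-level data from a two-arm randomised trial.

    Parameters
    ----------
    subject_id
        Opaque per-subject labels.
    Y
        Continuous outcome, higher is better.
    A
        Effect-coded arm, exactly -1/2 or +1/2 per subject.
    biomarkers
        Numeric biomarker matrix (one column per biomarker; categorical
        variables already expanded to indicators).
    roles
        Map biomarker name -> {"prognostic", "moderator", "both"}; must cover
        every biomarker column.
    pi
        Probability of randomisation to the treated arm, in (0, 1).
    """

    subject_id: tuple[str, ...]
    Y: np.ndarray
    A: np.ndarray
    biomarkers: pd.DataFrame
    roles: Mapping[str, str]
    pi: float = 0.5

    def __post_init__(self):
        Y = np.asarray(self.Y, dtype=float)
        A = np.asarray(self.A, dtype=float)
        object.__setattr__(self, "Y", Y)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "subject_id", tuple(str(s) for s in self.subject_id))
        object.__setattr__(self, "roles", dict(self.roles))
        n = len(self.subject_id)
        if not (Y.shape == A.shape == (n,)) or len(self.biomarkers) != n:
            raise DataError("subject_id, Y, A and biomarkers must have equal length")
        if np.isnan(Y).any():
            raise DataError("missing values in outcome Y are not allowed")
        if np.isnan(A).any():
            raise DataError("missing values in arm A are not allowed")
        if not np.all(np.isin(A, (TREATED, CONTROL))):
            raise CodingError("arm A must be effect-coded as exactly -1/2 or +1/2")
        if not (0.0 < self.pi < 1.0):
            raise DataError(f"randomisation probability pi={self.pi} outside (0, 1)")
        bio = self.biomarkers
        if set(self.roles) != set(bio.columns):
            missing = set(bio.columns) - set(self.roles)
            extra = set(self.roles) - set(bio.columns)
            raise SchemaError(
                f"roles must cover exactly the biomarker columns "
                f"(missing roles: {sorted(missing)}, unknown names: {sorted(extra)})"
            )
        for name, role in self.roles.items():
            if role not in VALID_ROLES:
                raise SchemaError(f"unknown role {role!r} for biomarker {name!r}")
        values = bio.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise DataError("biomarker columns must be numeric after expansion")
        if values.size and np.isnan(values.astype(float)).any():
            raise DataError("missing biomarker values are not allowed")
        _check_indicator_groups(bio)

    # -- convenience views -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.subject_id)

    @property
    def treated_mask(self) -> np.ndarray:
        return self.A > 0

    @property
    def control_mask(self) -> np.ndarray:
        return self.A < 0

    @property
    def n_treated(self) -> int:
        return int(self.treated_mask.sum())

    @property
    def n_control(self) -> int:
        return int(self.control_mask.sum())

    @property
    def moderator_names(self) -> list[str]:
        """Candidate moderators: role ``moderator`` or ``both``, column order."""
        return [c for c in self.biomarkers.columns
                if self.roles[c] in (ROLE_MODERATOR, ROLE_BOTH)]

    @property
    def prognostic_names(self) -> list[str]:
        """Prognostic variables: role ``prognostic`` or ``both``, column order."""
        return [c for c in self.biomarkers.columns
                if self.roles[c] in (ROLE_PROGNOSTIC, ROLE_BOTH)]

    def subset(self, indices) -> "TrialData":
        """Row subset/resample (used for splits and bootstrap resamples)."""
        idx = np.asarray(indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return TrialData(
            subject_id=tuple(self.subject_id[i] for i in idx),
            Y=self.Y[idx],
            A=self.A[idx],
            biomarkers=self.biomarkers.iloc[idx].reset_index(drop=True),
            roles=self.roles,
            pi=self.pi,
        )


def _check_indicator_groups(bio: pd.DataFrame) -> None:
    """Indicator columns 'name.level' of one categorical must be exclusive."""
    groups: dict[str, list[str]] = {}
    for col in bio.columns:
        if "." in col:
            groups.setdefault(col.rsplit(".", 1)[0], []).append(col)
    for base, cols in groups.items():
        if len(cols) < 2:
            continue
        vals = bio[cols].to_numpy(dtype=float)
        if not np.all(np.isin(vals, (0.0, 1.0))):
            continue  # dotted names that are not indicators
        if (vals.sum(axis=1) > 1).any():
            raise DataError(
                f"indicator columns {cols} for categorical {base!r} are not "
                f"mutually exclusive"
            )


def toy_trial() -> TrialData:
    """The fixed hand-checkable 4-subject trial used in worked examples.

    Two treated subjects (T1, T2) and two controls (C1, C2), one moderator
    Z1 and one prognostic variable X1, 1:1 randomisation.  Every estimator in
    this package has a closed-form hand computation on this fixture.
    """
    return TrialData(
        subject_id=("T1", "T2", "C1", "C2"),
        Y=np.array([3.0, 1.0, 0.0, 2.0]),
        A=np.array([TREATED, TREATED, CONTROL, CONTROL]),
        biomarkers=pd.DataFrame({"Z1": [1.0, 0.0, 1.0, 1.0],
                                 "X1": [2.0, 0.0, 0.0, 2.0]}),
        roles={"Z1": ROLE_MODERATOR, "X1": ROLE_PROGNOSTIC},
        pi=0.5,
    )


# ---------------------------------------------------------------------------
# Schema + delimited I/O
# ---------------------------------------------------------------------------

def _load_schema(schema) -> dict:
    if isinstance(schema, (str, Path)):
        with open(schema) as fh:
            schema = yaml.safe_load(fh)
    if not isinstance(schema, Mapping):
        raise SchemaError("schema must be a mapping or a path to a YAML mapping")
    schema = dict(schema)
    for key in ("outcome", "arm", "roles"):
        if key not in schema:
            raise SchemaError(f"schema is missing required key {key!r}")
    return schema


def read_trial(path, schema) -> TrialData:
    """Read a delimited trial table plus its role schema.

    ``schema`` is a mapping (or path to a YAML file) with keys:

    - ``outcome``: outcome column name
    - ``arm``: arm column name (coded 0/1 or +/-1/2; recoded to +/-1/2)
    - ``roles``: biomarker name -> role
    - ``id`` (optional): subject-id column; generated if absent
    - ``pi`` (optional, default 0.5)
    - ``categorical`` (optional): columns to force-expand to indicators
    - ``reference`` (optional): categorical column -> reference level
    """
    schema = _load_schema(schema)
    df = pd.read_csv(path, float_precision="round_trip")
    outcome, arm = schema["outcome"], schema["arm"]
    roles_in: Mapping[str, str] = schema["roles"]
    for col in (outcome, arm, *roles_in):
        if col not in df.columns:
            raise SchemaError(f"declared column {col!r} not found in {path}")

    if df[outcome].isna().any():
        raise DataError(f"missing values in outcome column {outcome!r}")
    if df[arm].isna().any():
        raise DataError(f"missing values in arm column {arm!r}")
    Y = df[outcome].to_numpy(dtype=float)
    A = _recode_arm(df[arm])

    categorical = set(schema.get("categorical") or ())
    reference = dict(schema.get("reference") or {})
    bio_cols: dict[str, np.ndarray] = {}
    roles: dict[str, str] = {}
    for name, role in roles_in.items():
        col = df[name]
        if name in categorical or not pd.api.types.is_numeric_dtype(col):
            levels = sorted(col.astype(str).unique())
            ref = str(reference.get(name, levels[0]))
            if ref not in levels:
                raise SchemaError(
                    f"reference level {ref!r} not among levels {levels} of {name!r}")
            for lvl in levels:
                if lvl == ref:
                    continue
                ind = f"{name}.{lvl}"
                bio_cols[ind] = (col.astype(str) == lvl).to_numpy(dtype=float)
                roles[ind] = role
        else:
            if col.isna().any():
                raise DataError(f"missing values in biomarker column {name!r}")
            bio_cols[name] = col.to_numpy(dtype=float)
            roles[name] = role

    id_col = schema.get("id")
    if id_col is not None and id_col in df.columns:
        subject_id = tuple(df[id_col].astype(str))
    elif "subject_id" in df.columns:
        subject_id = tuple(df["subject_id"].astype(str))
    else:
        subject_id = tuple(f"S{i + 1}" for i in range(len(df)))

    return TrialData(
        subject_id=subject_id,
        Y=Y,
        A=A,
        biomarkers=pd.DataFrame(bio_cols),
        roles=roles,
        pi=float(schema.get("pi", 0.5)),
    )


def _recode_arm(col: pd.Series) -> np.ndarray:
    vals = col.to_numpy(dtype=float)
    distinct = set(np.unique(vals))
    if len(distinct) > 2:
        raise CodingError(
            f"arm column has {len(distinct)} distinct values; expected a "
            f"binary coding (0/1 or -1/2,+1/2)")
    if distinct <= {CONTROL, TREATED}:
        return vals
    if distinct <= {0.0, 1.0}:
        return np.where(vals == 1.0, TREATED, CONTROL)
    raise CodingError(f"unrecognised arm coding with values {sorted(distinct)}")


def write_trial(data: TrialData, path, schema_path=None) -> None:
    """Write a TrialData to CSV plus a YAML role-schema sidecar.

    ``read_trial(path, sidecar)`` reproduces the data exactly: floats are
    written with Python's shortest round-tripping representation.  The sidecar
    defaults to ``<path>.schema.yaml``.
    """
    path = Path(path)
    out = pd.DataFrame({"subject_id": list(data.subject_id),
                        "Y": data.Y, "A": data.A})
    for col in data.biomarkers.columns:
        out[col] = data.biomarkers[col].to_numpy()
    out.to_csv(path, index=False)
    schema = {
        "outcome": "Y",
        "arm": "A",
        "id": "subject_id",
        "pi": float(data.pi),
        "roles": dict(data.roles),
    }
    if schema_path is None:
        schema_path = path.with_name(path.name + ".schema.yaml")
    with open(schema_path, "w") as fh:
        yaml.safe_dump(schema, fh, sort_keys=False)


def trials_equal(a: TrialData, b: TrialData) -> bool:
    """Exact equality of two TrialData objects (used to verify round trips)."""
    return (
        a.subject_id == b.subject_id
        and np.array_equal(a.Y, b.Y)
        and np.array_equal(a.A, b.A)
        and list(a.biomarkers.columns) == list(b.biomarkers.columns)
        and np.array_equal(a.biomarkers.to_numpy(), b.biomarkers.to_numpy())
        and dict(a.roles) == dict(b.roles)
        and a.pi == b.pi
    )
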