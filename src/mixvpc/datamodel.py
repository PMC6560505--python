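"""Core domain types and I/O for NONMEM-style PK datasets and phm-like tables.

The long format follows NONMEM conventions: one row per event, with
``EVID=1`` marking dose records (``AMT`` in mg) and ``EVID=0`` marking
observation records (``DV`` in mg/L); ``MDV=1`` flags a missing dependent
variable.  Times are absolute hours from first dose.  Covariates are
constant within a subject and read from the subject's first row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DoseEvent",
    "Observation",
    "SubjectData",
    "Dataset",
    "ResidualSpec",
    "MixtureParameters",
    "IndividualMixtureRecord",
    "FitResult",
    "DatasetFormatError",
    "DatasetValidationError",
    "read_dataset",
    "write_dataset",
    "write_phm_table",
    "read_phm_table",
    "save_parameters",
    "load_parameters",
]

ROUTE_ORAL = "oral-first-order"
ROUTE_BOLUS = "bolus-central"
_ROUTES = (ROUTE_ORAL, ROUTE_BOLUS)


class DatasetFormatError(ValueError):
    """Raised when a file does not follow the expected layout."""


class DatasetValidationError(ValueError):
    """Raised when file content violates a dataset invariant."""


@dataclass(frozen=True)
class DoseEvent:
    """A single dose: absolute time (h), amount (mg) and administration route."""

    time: float
    amount: float
    route: str = ROUTE_ORAL

    def __post_init__(self):
        if not (math.isfinite(self.time) and self.time >= 0):
            raise DatasetValidationError(f"dose time must be finite and >= 0, got {self.time}")
        if not (math.isfinite(self.amount) and self.amount > 0):
            raise DatasetValidationError(f"dose amount must be > 0, got {self.amount}")
        if self.route not in _ROUTES:
            raise DatasetValidationError(f"unknown route {self.route!r}; expected one of {_ROUTES}")


@dataclass(frozen=True)
class Observation:
    """A concentration record: time (h), value (mg/L) and missing flag."""

    time: float
    value: float
    missing: bool = False

    def __post_init__(self):
        if not (math.isfinite(self.time) and self.time >= 0):
            raise DatasetValidationError(f"observation time must be finite and >= 0, got {self.time}")


@dataclass
class SubjectData:
    id: str
    doses: list = field(default_factory=list)
    observations: list = field(default_factory=list)
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        times = [o.time for o in self.observations]
        if times != sorted(times):
            self.observations = sorted(self.observations, key=lambda o: o.time)

    @property
    def obs_times(self) -> np.ndarray:
        return np.array([o.time for o in self.observations], dtype=float)

    @property
    def obs_values(self) -> np.ndarray:
        return np.array([o.value for o in self.observations], dtype=float)

    @property
    def obs_missing(self) -> np.ndarray:
        return np.array([o.missing for o in self.observations], dtype=bool)


@dataclass
class Dataset:
    subjects: list
    design_label: str = ""

    def __post_init__(self):
        ids = [s.id for s in self.subjects]
        if len(ids) != len(set(ids)):
            raise DatasetValidationError("subject ids must be unique within a dataset")

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def n_observations(self) -> int:
        return sum(len(s.observations) for s in self.subjects)


@dataclass(frozen=True)
class ResidualSpec:
    """Residual unexplained variability model.

    kind: 'proportional' (var ∝ prediction²), 'additive', or 'combined'.
    Variances, not standard deviations.
    """

    kind: str = "proportional"
    prop_var: float = 0.0
    add_var: float = 0.0

    def __post_init__(self):
        if self.kind not in ("proportional", "additive", "combined"):
            raise ValueError(f"unknown residual model {self.kind!r}")
        if self.prop_var < 0 or self.add_var < 0:
            raise ValueError("residual variances must be non-negative")
        if self.kind == "proportional" and self.prop_var <= 0:
            raise ValueError("proportional residual model requires prop_var > 0")
        if self.kind == "additive" and self.add_var <= 0:
            raise ValueError("additive residual model requires add_var > 0")

    def variance(self, pred):
        """Observation variance given the model prediction (vectorized)."""
        pred = np.asarray(pred, dtype=float)
        if self.kind == "proportional":
            return self.prop_var * pred**2
        if self.kind == "additive":
            return np.full_like(pred, self.add_var)
        return self.prop_var * pred**2 + self.add_var


@dataclass
class MixtureParameters:
    """Population-level parameters of a (possibly one-component) mixture model.

    theta_component : per-component typical values for the parameters that
        differ between subpopulations (e.g. ``[{"CL": 20}, {"CL": 80}]``).
    theta_shared : typical values common to all components (ka, V, Vmax, ...).
    pmix : mixing proportions over components (sums to 1).
    omega : diagonal interindividual variances keyed by parameter name;
        random effects act multiplicatively as ``typical * exp(eta)``.
    sigma : residual-error specification.
    """

    theta_component: list
    theta_shared: dict
    pmix: np.ndarray
    omega: dict
    sigma: ResidualSpec

    def __post_init__(self):
        self.pmix = np.asarray(self.pmix, dtype=float)
        if len(self.theta_component) != len(self.pmix):
            raise ValueError("theta_component and pmix must have the same length")
        if np.any(self.pmix < 0) or np.any(self.pmix > 1):
            raise ValueError("pmix entries must lie in [0, 1]")
        if abs(self.pmix.sum() - 1.0) > 1e-12:
            raise ValueError(f"pmix must sum to 1, got {self.pmix.sum()!r}")
        for d in self.theta_component:
            for name, v in d.items():
                if not v > 0:
                    raise ValueError(f"typical value {name} must be > 0, got {v}")
        for name, v in self.theta_shared.items():
            if not v > 0:
                raise ValueError(f"typical value {name} must be > 0, got {v}")
        for name, v in self.omega.items():
            if not v > 0:
                raise ValueError(f"omega variance for {name} must be > 0, got {v}")

    @property
    def n_components(self) -> int:
        return len(self.pmix)

    def component_typicals(self, k: int) -> dict:
        """Merged typical values for component ``k`` (0-based)."""
        merged = dict(self.theta_shared)
        merged.update(self.theta_component[k])
        return merged

    def to_dict(self) -> dict:
        return {
            "theta_component": [dict(d) for d in self.theta_component],
            "theta_shared": dict(self.theta_shared),
            "pmix": [float(p) for p in self.pmix],
            "omega": dict(self.omega),
            "sigma": {
                "kind": self.sigma.kind,
                "prop_var": self.sigma.prop_var,
                "add_var": self.sigma.add_var,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureParameters":
        return cls(
            theta_component=[dict(x) for x in d["theta_component"]],
            theta_shared=dict(d["theta_shared"]),
            pmix=np.asarray(d["pmix"], dtype=float),
            omega=dict(d["omega"]),
            sigma=ResidualSpec(**d["sigma"]),
        )

    def copy(self) -> "MixtureParameters":
        return MixtureParameters.from_dict(self.to_dict())


@dataclass
class IndividualMixtureRecord:
    """Per-individual mixture diagnostics: the content of a phm-like table.

    iofv : per-component −2·log marginal likelihood (2π constant excluded).
    il : per-component relative likelihood exp(−(iofv−min iofv)/2); the best
        component has il = 1 and ratios reflect iofv differences.
    ip : posterior subpopulation probabilities (IP_mix); a simplex.
    mixest : 1-based index of the most likely subpopulation (MIXEST).
    eta_mode : per-component conditional modes of the random effects,
        shape (n_components, n_eta); may be empty for table round-trips.
    """

    id: str
    iofv: np.ndarray
    il: np.ndarray
    ip: np.ndarray
    mixest: int
    eta_mode: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))

    def __post_init__(self):
        self.iofv = np.asarray(self.iofv, dtype=float)
        self.il = np.asarray(self.il, dtype=float)
        self.ip = np.asarray(self.ip, dtype=float)
        if abs(self.ip.sum() - 1.0) > 1e-10:
            raise ValueError(f"ip must sum to 1 within 1e-10, got {self.ip.sum()!r}")
        if not 1 <= self.mixest <= len(self.ip):
            raise ValueError(f"mixest must be a 1-based component index, got {self.mixest}")


@dataclass
class FitResult:
    params: MixtureParameters
    ofv: float
    records: list
    converged: bool
    n_function_evals: int
    best_start: int = 0
    pmix_at_bound: bool = False


# ---------------------------------------------------------------------------
# dataset I/O

_MANDATORY = ("ID", "TIME", "DV", "AMT", "EVID")


def read_dataset(path, column_map: dict | None = None, design_label: str = "") -> Dataset:
    """Read a NONMEM-flavored long-format CSV into a :class:`Dataset`.

    ``column_map`` optionally renames file columns to the canonical names,
    e.g. ``{"SUBJID": "ID"}``.  Unrecognized columns other than known
    covariates are carried as covariates; column order is irrelevant.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    for col in _MANDATORY:
        if col not in df.columns:
            raise DatasetFormatError(f"mandatory column {col!r} missing from {path}")
    if "MDV" not in df.columns:
        df["MDV"] = 0
    if "ROUTE" not in df.columns:
        df["ROUTE"] = ROUTE_ORAL

    bad = df.index[df["TIME"] < 0]
    if len(bad):
        raise DatasetValidationError(f"negative TIME at data row {int(bad[0]) + 1}")

    covariate_cols = [
        c for c in df.columns
        if c not in ("ID", "TIME", "DV", "AMT", "EVID", "MDV", "ROUTE")
    ]
    subjects = []
    for sid, g in df.groupby("ID", sort=False):
        doses, obs = [], []
        for idx, row in g.iterrows():
            if int(row["EVID"]) == 1:
                if not row["AMT"] > 0:
                    raise DatasetValidationError(
                        f"dose row with AMT <= 0 at data row {int(idx) + 1}"
                    )
                doses.append(DoseEvent(float(row["TIME"]), float(row["AMT"]), str(row["ROUTE"])))
            elif int(row["EVID"]) == 0:
                missing = int(row["MDV"]) == 1
                value = float(row["DV"]) if not missing else np.nan
                obs.append(Observation(float(row["TIME"]), value, missing))
            else:
                raise DatasetFormatError(
                    f"unsupported EVID {int(row['EVID'])} at data row {int(idx) + 1}"
                )
        covs = {}
        first = g.iloc[0]
        for c in covariate_cols:
            vals = g[c].to_numpy()
            if not np.all(vals == vals[0]):
                raise DatasetValidationError(
                    f"time-varying covariate {c!r} for subject {sid} is not supported"
                )
            covs[c] = float(first[c])
        subjects.append(SubjectData(str(sid), doses, obs, covs))
    return Dataset(subjects, design_label=design_label)


def write_dataset(dataset: Dataset, path) -> None:
    """Write a :class:`Dataset` back to NONMEM-flavored CSV."""
    rows = []
    for s in dataset.subjects:
        events = [("dose", d.time, d) for d in s.doses] + [
            ("obs", o.time, o) for o in s.observations
        ]
        # doses before observations at equal times, as a dose at t affects obs at t+
        events.sort(key=lambda e: (e[1], 0 if e[0] == "dose" else 1))
        for kind, _, ev in events:
            row = {"ID": s.id}
            if kind == "dose":
                row.update(TIME=ev.time, AMT=ev.amount, DV=0.0, EVID=1, MDV=1, ROUTE=ev.route)
            else:
                row.update(
                    TIME=ev.time,
                    AMT=0.0,
                    DV=0.0 if ev.missing else ev.value,
                    EVID=0,
                    MDV=int(ev.missing),
                    ROUTE="",
                )
            row.update(s.covariates)
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# phm-like table I/O

def write_phm_table(records: list, path) -> None:
    """Write per-(subject, component) mixture diagnostics as CSV.

    Columns: ID, SUBPOP (1-based), IOFV, IL, IPmix, MIXEST.  This carries the
    content of NONMEM's *.phm output in a plain-text layout.
    """
    if not records:
        raise ValueError("write_phm_table requires a non-empty record list")
    rows = []
    for r in records:
        for k in range(len(r.ip)):
            rows.append(
                {
                    "ID": r.id,
                    "SUBPOP": k + 1,
                    "IOFV": r.iofv[k],
                    "IL": r.il[k],
                    "IPmix": r.ip[k],
                    "MIXEST": r.mixest,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def read_phm_table(path) -> list:
    """Read a phm-like CSV back into :class:`IndividualMixtureRecord` objects."""
    df = pd.read_csv(path)
    records = []
    for sid, g in df.groupby("ID", sort=False):
        g = g.sort_values("SUBPOP")
        ip = g["IPmix"].to_numpy(dtype=float)
        ip = ip / ip.sum()  # normalize away the last-digit rounding of the text form
        records.append(
            IndividualMixtureRecord(
                id=str(sid),
                iofv=g["IOFV"].to_numpy(dtype=float),
                il=g["IL"].to_numpy(dtype=float),
                ip=ip,
                mixest=int(g["MIXEST"].iloc[0]),
            )
        )
    return records


def save_parameters(params: MixtureParameters, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def load_parameters(path) -> MixtureParameters:
    with open(path) as fh:
        return MixtureParameters.from_dict(yaml.safe_load(fh))
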