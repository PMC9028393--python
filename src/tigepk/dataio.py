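"""Dataset and configuration I/O.

Datasets use NONMEM-style event records: one row per dose (EVID=1, AMT in
mg, DUR in h) or observation (EVID=0, DV in mg/L, MDV=0), TIME in hours
since the subject's first dose, covariates constant within subject.  RATE
columns are accepted on input and converted (DUR = AMT/RATE).  Output is
canonical: fixed column order and number formatting, so write(read(x)) is
byte-identical for files this package wrote.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import asdict, dataclass, fields

import numpy as np
import pandas as pd
import yaml

from .estimation import StudyDataset, Subject
from .pk_core import DoseEvent

__all__ = [
    "read_dataset",
    "write_dataset",
    "dataset_to_frame",
    "RunConfig",
    "DatasetValidationError",
]

#: CSV column -> internal covariate name
COVARIATE_COLUMNS = {
    "WT": "weight", "AGE": "age", "SEX": "sex", "BILI": "bilirubin_tot",
    "ALB": "albumin", "INR": "inr", "ASC": "ascites", "SCR": "scr",
    "EGFR": "egfr", "MELD": "meld", "LIMAX": "limax", "CPS": "cps",
}
_EVENT_COLUMNS = ["ID", "TIME", "EVID", "AMT", "DUR", "DV", "MDV"]
_STRING_COVARIATES = {"SEX", "ASC", "CPS"}


class DatasetValidationError(ValueError):
    """A dataset file violated the event-record contract."""


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "."
    if isinstance(x, str):
        return x
    v = float(x)
    if v == int(v) and abs(v) < 1e15:
        return str(int(v))
    return format(v, ".6g")


def dataset_to_frame(dataset: StudyDataset) -> pd.DataFrame:
    """Event-record DataFrame in canonical column order."""
    rows = []
    for s in dataset.subjects:
        cov_cols = {
            col: s.covariates[name]
            for col, name in COVARIATE_COLUMNS.items() if name in s.covariates
        }
        events = [
            {"ID": s.id, "TIME": d.start_time, "EVID": 1, "AMT": d.amount,
             "DUR": d.infusion_duration, "DV": None, "MDV": 1, **cov_cols}
            for d in s.doses
        ] + [
            {"ID": s.id, "TIME": t, "EVID": 0, "AMT": None, "DUR": None,
             "DV": dv, "MDV": 0, **cov_cols}
            for t, dv in zip(s.times, s.dv)
        ]
        # stable order: time, doses before observations at equal time
        events.sort(key=lambda r: (r["TIME"], -r["EVID"]))
        rows.extend(events)
    frame = pd.DataFrame(rows)
    cols = _EVENT_COLUMNS + [c for c in COVARIATE_COLUMNS if c in frame.columns]
    return frame.reindex(columns=cols)


def write_dataset(dataset: StudyDataset, path) -> None:
    """Write a dataset as canonical NONMEM-style CSV (deterministic)."""
    frame = dataset_to_frame(dataset)
    buf = io.StringIO()
    buf.write(",".join(frame.columns) + "\n")
    for _, row in frame.iterrows():
        buf.write(",".join(_fmt(v) for v in row) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_dataset(path) -> StudyDataset:
    """Read and validate a NONMEM-style CSV into a :class:`StudyDataset`.

    Raises :class:`DatasetValidationError` naming the offending subject and
    line for: missing required columns, an observation before any dose,
    non-positive DV, DV on a dose row, non-monotone times within a subject,
    or time-varying covariates.
    """
    raw = pd.read_csv(path, na_values=["."], dtype={"ID": str},
                      keep_default_na=True, comment="#")
    missing = [c for c in ("ID", "TIME", "EVID") if c not in raw.columns]
    if missing:
        raise DatasetValidationError(f"missing required column(s): {missing}")
    if "DV" not in raw.columns:
        raise DatasetValidationError("missing required column(s): ['DV']")
    if "AMT" not in raw.columns:
        raise DatasetValidationError("missing required column(s): ['AMT']")
    if "DUR" not in raw.columns and "RATE" not in raw.columns:
        raise DatasetValidationError("need a DUR or RATE column for infusion durations")

    subjects = []
    for sid, grp in raw.groupby("ID", sort=False):
        times = grp["TIME"].to_numpy(dtype=float)
        if np.any(np.diff(times) < 0):
            raise DatasetValidationError(f"subject {sid}: TIME not non-decreasing")
        doses, obs_t, obs_dv = [], [], []
        seen_dose = False
        for line, (_, row) in zip(grp.index + 2, grp.iterrows()):  # header = line 1
            evid = int(row["EVID"])
            if evid == 1:
                amt = float(row["AMT"])
                if not np.isnan(row.get("DV", np.nan)):
                    raise DatasetValidationError(
                        f"subject {sid}, line {line}: dose row carries a DV")
                if "DUR" in raw.columns and not pd.isna(row["DUR"]):
                    dur = float(row["DUR"])
                elif "RATE" in raw.columns and not pd.isna(row["RATE"]):
                    dur = amt / float(row["RATE"])
                else:
                    raise DatasetValidationError(
                        f"subject {sid}, line {line}: dose row lacks DUR/RATE")
                doses.append(DoseEvent(float(row["TIME"]), amt, dur))
                seen_dose = True
            elif evid == 0:
                if not seen_dose:
                    raise DatasetValidationError(
                        f"subject {sid}, line {line}: observation before any dose")
                dv = row["DV"]
                if pd.isna(dv) or float(dv) <= 0:
                    raise DatasetValidationError(
                        f"subject {sid}, line {line}: observation DV must be > 0")
                obs_t.append(float(row["TIME"]))
                obs_dv.append(float(dv))
            else:
                raise DatasetValidationError(
                    f"subject {sid}, line {line}: unsupported EVID {evid}")
        covs = {}
        for col, name in COVARIATE_COLUMNS.items():
            if col in raw.columns:
                vals = grp[col].dropna().unique()
                if len(vals) > 1:
                    raise DatasetValidationError(
                        f"subject {sid}: covariate {col} varies within subject")
                if len(vals) == 1:
                    v = vals[0]
                    covs[name] = str(v) if col in _STRING_COVARIATES else float(v)
        if not doses:
            raise DatasetValidationError(f"subject {sid}: no dose events")
        if not obs_t:
            raise DatasetValidationError(f"subject {sid}: no observations")
        subjects.append(Subject(id=str(sid), doses=doses,
                                times=np.asarray(obs_t), dv=np.asarray(obs_dv),
                                covariates=covs))
    return StudyDataset(subjects=subjects)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Validated configuration for the pipeline commands.

    Unknown keys are rejected; all stochastic routines draw their seeds from
    here so runs with an identical config (identical hash) are bit-identical.
    """

    model: str = "base"
    cl_preset: str = "headline"
    seed: int = 1
    n_subjects: int = 39
    estimation_maxiter: int = 400
    sim_n: int = 1000
    n_sim_vpc: int = 500
    vpc_bins: int = 5
    n_boot: int = 200
    reference: str = "default"  # or "alt"
    rule: str | None = None  # key into dosing.STUDY_RULES
    mic_grid: tuple = ()
    target: str = "ciai"  # or "cssi"

    def __post_init__(self) -> None:
        if self.model not in ("base", "A", "B", "C"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.cl_preset not in ("headline", "final_model"):
            raise ValueError(f"unknown cl_preset {self.cl_preset!r}")
        if self.target not in ("ciai", "cssi"):
            raise ValueError(f"unknown target {self.target!r}")
        if self.reference not in ("default", "alt"):
            raise ValueError(f"unknown reference {self.reference!r}")
        for nm in ("seed", "n_subjects", "sim_n", "n_sim_vpc", "vpc_bins", "n_boot"):
            if int(getattr(self, nm)) < 0:
                raise ValueError(f"{nm} must be >= 0")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown config key(s): {unknown}")
        if "mic_grid" in data:
            data = {**data, "mic_grid": tuple(data["mic_grid"])}
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self) -> str:
        d = asdict(self)
        d["mic_grid"] = list(d["mic_grid"])
        return yaml.safe_dump(d, sort_keys=True)

    @property
    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]
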