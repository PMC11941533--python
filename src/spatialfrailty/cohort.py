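"""Cohort I/O: read, validate and encode right-censored NICU survival records.

The cohort table is a CSV with one row per neonate and columns

    time, status, ga_weeks, b_weight, platelet, hemorrhage, pt_aptt, block

``time`` is hours spent in the NICU (positive, continuous; exact ties are
allowed — the likelihood is fully parametric, not a partial likelihood),
``status`` is the event indicator (1 = death, 0 = discharged alive /
censored), and ``block`` is the administrative block of residence used for
the spatial frailty.  Covariates enter the model untransformed: hemorrhage
is one ordinal numeric column (0 = none, 1 = intraventricular,
2 = intracerebral), PT_APTT coagulation status is 0/1, and platelet counts
stay on their raw 10^3/uL scale.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = (
    "time",
    "status",
    "ga_weeks",
    "b_weight",
    "platelet",
    "hemorrhage",
    "pt_aptt",
    "block",
)

#: fixed covariate order of the design matrix (and of beta everywhere)
COVARIATE_ORDER = ("ga_weeks", "b_weight", "platelet", "hemorrhage", "pt_aptt")

__all__ = [
    "REQUIRED_COLUMNS",
    "COVARIATE_ORDER",
    "CohortSchemaError",
    "CohortValidationError",
    "CohortRecord",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "cohort_from_frame",
    "summarize_cohort",
    "encode_design",
    "export_frailty_table",
]


class CohortSchemaError(ValueError):
    """The CSV header is missing a required column."""


class CohortValidationError(ValueError):
    """A row violates a cohort invariant (with its row index in the message)."""


@dataclass(frozen=True)
class CohortRecord:
    time: float
    status: int
    ga_weeks: float
    b_weight: float
    platelet: float
    hemorrhage: int
    pt_aptt: int
    block: str


@dataclass
class Cohort:
    """Validated cohort: a record table plus the ordered block list."""

    frame: pd.DataFrame
    blocks: list[str]
    covariate_order: tuple[str, ...] = COVARIATE_ORDER

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def time(self) -> np.ndarray:
        return self.frame["time"].to_numpy(dtype=float)

    @property
    def status(self) -> np.ndarray:
        return self.frame["status"].to_numpy(dtype=float)

    @property
    def n_events(self) -> int:
        return int(self.frame["status"].sum())

    @property
    def event_fraction(self) -> float:
        return self.n_events / self.n

    @property
    def records(self) -> list[CohortRecord]:
        return [
            CohortRecord(
                time=float(r.time),
                status=int(r.status),
                ga_weeks=float(r.ga_weeks),
                b_weight=float(r.b_weight),
                platelet=float(r.platelet),
                hemorrhage=int(r.hemorrhage),
                pt_aptt=int(r.pt_aptt),
                block=str(r.block),
            )
            for r in self.frame.itertuples(index=False)
        ]


def _validate_rows(df: pd.DataFrame, blocks: Sequence[str]) -> None:
    block_set = set(blocks)
    for idx, row in enumerate(df.itertuples(index=False)):
        if not np.isfinite(row.time) or row.time <= 0:
            raise CohortValidationError(f"row {idx}: time must be > 0, got {row.time}")
        if row.status not in (0, 1):
            raise CohortValidationError(
                f"row {idx}: status must be 0 or 1, got {row.status}"
            )
        if row.hemorrhage not in (0, 1, 2):
            raise CohortValidationError(
                f"row {idx}: hemorrhage must be in {{0,1,2}}, got {row.hemorrhage}"
            )
        if row.pt_aptt not in (0, 1):
            raise CohortValidationError(
                f"row {idx}: pt_aptt must be 0 or 1, got {row.pt_aptt}"
            )
        if str(row.block) not in block_set:
            raise CohortValidationError(
                f"row {idx}: block {row.block!r} not in declared blocks {sorted(block_set)}"
            )


def cohort_from_frame(df: pd.DataFrame, block_set: Sequence[str] | None = None) -> Cohort:
    """Validate an in-memory table and wrap it as a Cohort."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df.loc[:, list(REQUIRED_COLUMNS)].reset_index(drop=True)
    df["block"] = df["block"].astype(str)
    blocks = (
        [str(b) for b in block_set]
        if block_set is not None
        else sorted(df["block"].unique())
    )
    _validate_rows(df, blocks)
    return Cohort(frame=df, blocks=list(blocks))


def read_cohort(path, block_set: Sequence[str] | None = None) -> Cohort:
    """Read and validate a cohort CSV.

    The block list defaults to the sorted set of observed labels; pass
    ``block_set`` to declare blocks (e.g. blocks with no admissions).
    """
    df = pd.read_csv(path)
    return cohort_from_frame(df, block_set=block_set)


def write_cohort(cohort: Cohort, path) -> None:
    """Write the cohort back to CSV (inverse of read_cohort)."""
    cohort.frame.to_csv(path, index=False)


def encode_design(cohort: Cohort) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix X (n x 5, covariate order) and block index vector.

    Covariates are untransformed: hemorrhage as a single ordinal 0/1/2
    column, pt_aptt as 0/1, no centering or standardization.
    """
    X = cohort.frame[list(cohort.covariate_order)].to_numpy(dtype=float)
    block_pos = {b: i for i, b in enumerate(cohort.blocks)}
    block_idx = cohort.frame["block"].map(block_pos).to_numpy(dtype=int)
    return X, block_idx


_STAT_COLUMNS = ("min", "q1", "median", "mean", "q3", "max", "sd")


def _describe(values: np.ndarray) -> dict[str, float]:
    out = {
        "min": float(np.min(values)),
        "q1": float(np.quantile(values, 0.25)),
        "median": float(np.median(values)),
        "mean": float(np.mean(values)),
        "q3": float(np.quantile(values, 0.75)),
        "max": float(np.max(values)),
    }
    # SD with the n-1 denominator; undefined (NaN) for singleton strata
    out["sd"] = float(np.std(values, ddof=1)) if len(values) >= 2 else float("nan")
    return out


def summarize_cohort(cohort: Cohort) -> pd.DataFrame:
    """Descriptive statistics per covariate, stratified by outcome.

    Returns one row per (stratum, covariate) with min/Q1/median/mean/Q3/max
    and the sample SD; strata are ``survived`` (status 0), ``died``
    (status 1) and ``total``.  A stratum with fewer than two records gets an
    undefined (NaN) SD rather than an error.
    """
    df = cohort.frame
    strata = {
        "survived": df[df["status"] == 0],
        "died": df[df["status"] == 1],
        "total": df,
    }
    rows = []
    for name, sub in strata.items():
        for cov in cohort.covariate_order:
            if len(sub) == 0:
                continue
            stats = _describe(sub[cov].to_numpy(dtype=float))
            rows.append({"stratum": name, "n": len(sub), "covariate": cov, **stats})
    return pd.DataFrame(rows, columns=["stratum", "n", "covariate", *_STAT_COLUMNS])


FRAILTY_SIGN_NOTE = (
    "# positive posterior frailty values indicate an increase in the risk; "
    "negative values a decrease"
)


def export_frailty_table(blocks: Sequence[str], frailties: Sequence[float], path) -> None:
    """Write per-block posterior mean frailties as a CSV joinable to GIS layers.

    The file carries a header comment documenting the sign convention and
    two columns ``block,frailty``.  Values are written as-is (no
    recentring at export).
    """
    blocks = list(blocks)
    frailties = np.asarray(frailties, dtype=float)
    if len(blocks) == 0:
        raise ValueError("block list is empty")
    if len(blocks) != len(frailties):
        raise ValueError(
            f"{len(blocks)} blocks but {len(frailties)} frailties"
        )
    buf = io.StringIO()
    buf.write(FRAILTY_SIGN_NOTE + "\n")
    pd.DataFrame({"block": blocks, "frailty": frailties}).to_csv(buf, index=False)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def read_frailty_table(path) -> pd.DataFrame:
    """Read a frailty CSV written by :func:`export_frailty_table`."""
    return pd.read_csv(path, comment="#")
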