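"""Trial-level data structures, I/O, preprocessing, and RT-quantile summaries.

The central container is :class:`TrialTable`, a thin wrapper around a tidy
:class:`pandas.DataFrame` of two-choice RT trials keyed by subject, session
(drug vs. placebo) and cue (speed vs. accuracy emphasis).  RTs are stored in
milliseconds on disk and converted to seconds for modelling.  Summaries are
defective RT quantiles: per-cell quantiles of correct and error responses
together with the proportion correct, the representation both accumulator
models are fitted against and that vincentizing averages across subjects.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SESSIONS = ("drug", "placebo")
CUES = ("speed", "accuracy")
#: cue label used for dummy (fixation-only) trials emitted by the generator
DUMMY_CUE = "dummy"
#: default quantile probabilities for defective RT summaries
DEFAULT_PROBS = (0.1, 0.3, 0.5, 0.7, 0.9)
#: minimum number of error responses for error quantiles to be trusted;
#: below this the error mass is collapsed into a single bin for fitting
SPARSE_ERROR_MIN = 5

REQUIRED_COLUMNS = (
    "subject", "session", "block", "cue", "direction", "response",
    "correct", "rt_ms", "responded",
)


class SchemaError(ValueError):
    """Input table is missing required columns."""


class RowError(ValueError):
    """One or more rows violate trial invariants."""

    def __init__(self, message: str, rows: Sequence[int]):
        super().__init__(message)
        self.rows = list(rows)


class PreprocessingError(ValueError):
    """Preprocessing produced an empty design cell."""


@dataclass
class TrialTable:
    """Tidy trial-level table plus free-form provenance metadata."""

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "TrialTable":
        return TrialTable(self.df.copy(), json.loads(json.dumps(self.metadata)))

    @property
    def subjects(self) -> list:
        return sorted(self.df["subject"].unique().tolist())

    def rt_seconds(self) -> pd.Series:
        """RTs in seconds (NaN for non-responses)."""
        return self.df["rt_ms"] / 1000.0

    def cell(self, session: str, cue: str, subject=None) -> pd.DataFrame:
        m = (self.df["session"] == session) & (self.df["cue"] == cue)
        if subject is not None:
            m &= self.df["subject"] == subject
        return self.df.loc[m]

    def equals(self, other: "TrialTable") -> bool:
        """Field-by-field equality of the trial records (metadata ignored)."""
        a = self.df.reset_index(drop=True)
        b = other.df.reset_index(drop=True)
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for col in a.columns:
            if a[col].dtype.kind == "f" or b[col].dtype.kind == "f":
                ok = np.allclose(a[col].astype(float), b[col].astype(float),
                                 equal_nan=True, rtol=0, atol=1e-9)
            else:
                ok = a[col].equals(b[col])
            if not ok:
                return False
        return True


@dataclass
class QuantileSummary:
    """Defective RT quantiles and response proportions for one design cell."""

    session: str
    cue: str
    n_trials: int
    n_correct: int
    n_error: int
    p_correct: float
    probs: tuple
    correct_quantiles: np.ndarray
    error_quantiles: np.ndarray | None  # None when the error count is sparse
    sparse_errors: bool

    @property
    def cell(self) -> tuple:
        return (self.session, self.cue)

    def __post_init__(self):
        if not 0.0 <= self.p_correct <= 1.0:
            raise ValueError(f"p_correct {self.p_correct} outside [0, 1]")
        if np.any(np.diff(self.correct_quantiles) < -1e-12):
            raise ValueError("correct quantiles must be nondecreasing")
        if self.error_quantiles is not None and np.any(
                np.diff(self.error_quantiles) < -1e-12):
            raise ValueError("error quantiles must be nondecreasing")


def _validate_rows(df: pd.DataFrame) -> list[tuple[int, str]]:
    problems: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        if row.session not in SESSIONS:
            problems.append((i, f"session {row.session!r} not in {SESSIONS}"))
        if row.cue not in CUES + (DUMMY_CUE,):
            problems.append((i, f"cue {row.cue!r} not recognised"))
        if row.responded:
            if not np.isfinite(row.rt_ms) or row.rt_ms <= 0:
                problems.append((i, f"responded trial with rt_ms {row.rt_ms!r}"))
            if row.response not in ("left", "right"):
                problems.append((i, f"responded trial with response {row.response!r}"))
            elif row.cue != DUMMY_CUE and bool(row.correct) != (row.response == row.direction):
                problems.append((i, "correct flag inconsistent with response/direction"))
        else:
            if row.response not in ("none", "", None):
                problems.append((i, f"non-response trial with response {row.response!r}"))
    return problems


def read_trials(path, dialect: Mapping | None = None) -> TrialTable:
    """Read a delimited trial table, validating schema and row invariants.

    Parameters
    ----------
    path : str, Path or file-like
        Location of a delimited text file with a header row.
    dialect : mapping, optional
        Format options forwarded to :func:`pandas.read_csv` (e.g. ``sep``).

    Raises
    ------
    SchemaError
        If a required column is absent.
    RowError
        If rows violate trial invariants; the offending row numbers
        (0-based, excluding the header) are listed in the message.
    """
    opts = dict(dialect or {})
    opts.setdefault("sep", ",")
    df = pd.read_csv(path, **opts)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    df = df.copy()
    df["responded"] = df["responded"].astype(bool)
    df["response"] = df["response"].fillna("none")
    # rt may be blank for non-responses
    df["rt_ms"] = pd.to_numeric(df["rt_ms"], errors="coerce")
    bad_rt = df.index[(df["responded"]) & (~np.isfinite(df["rt_ms"]))].tolist()
    problems = _validate_rows(df)
    if bad_rt:
        problems += [(i, "unparseable rt_ms on responded trial") for i in bad_rt]
    if problems:
        rows = sorted({i for i, _ in problems})
        detail = "; ".join(f"row {i}: {msg}" for i, msg in sorted(problems)[:10])
        raise RowError(f"invalid rows {rows}: {detail}", rows)
    df["correct"] = df["correct"].fillna(False).astype(bool)
    df["block"] = df["block"].astype(int)
    return TrialTable(df.reset_index(drop=True), {"source": str(path)})


def write_trials(table: TrialTable, path, dialect: Mapping | None = None) -> None:
    """Write a trial table in the on-disk dialect (RTs in milliseconds)."""
    opts = dict(dialect or {})
    opts.setdefault("sep", ",")
    df = table.df.copy()
    table_path = Path(path)
    df.to_csv(table_path, index=False, **opts)
    if table.metadata:
        meta_path = table_path.with_suffix(table_path.suffix + ".meta.json")
        meta_path.write_text(json.dumps(table.metadata, indent=1, sort_keys=True))


def preprocess(table: TrialTable) -> TrialTable:
    """Prepare a raw trial table for modelling.

    Removes dummy trials, drops non-response trials, and collapses the
    left/right direction factor (only the correct/error coding is retained).
    Counts of removed trials are recorded in the metadata; the operation is
    idempotent.

    Raises
    ------
    PreprocessingError
        If any (subject, session, cue) cell ends up empty.
    """
    df = table.df
    n_dummy = int((df["cue"] == DUMMY_CUE).sum())
    df = df[df["cue"] != DUMMY_CUE]
    n_noresp = int((~df["responded"]).sum())
    df = df[df["responded"]].copy()
    for col in ("direction", "response", "feedback"):
        if col in df.columns:
            df = df.drop(columns=col)
    meta = dict(table.metadata)
    meta["n_dummy_removed"] = n_dummy + meta.get("n_dummy_removed", 0)
    meta["n_no_response_removed"] = n_noresp + meta.get("n_no_response_removed", 0)
    meta["preprocessed"] = True
    out = TrialTable(df.reset_index(drop=True), meta)
    before = table.df[table.df["cue"] != DUMMY_CUE]
    had = set(map(tuple, before[["subject", "session", "cue"]]
                  .drop_duplicates().itertuples(index=False)))
    have = set(map(tuple, df[["subject", "session", "cue"]]
                   .drop_duplicates().itertuples(index=False)))
    emptied = had - have
    if emptied:
        subject, session, cue = sorted(emptied)[0]
        raise PreprocessingError(
            f"empty cell after preprocessing: subject={subject!r} "
            f"session={session} cue={cue}")
    return out


def apply_subject_exclusions(table: TrialTable, min_accuracy: float = 0.60,
                             per_session: bool = False) -> TrialTable:
    """Exclude subjects with poor accuracy-cue performance.

    A subject is removed when their proportion correct on accuracy-cue
    trials falls strictly below ``min_accuracy``.  By default performance is
    pooled over both sessions; with ``per_session=True`` a subject failing
    the criterion in either session is excluded.
    """
    df = table.df
    acc_trials = df[df["cue"] == "accuracy"]
    excluded: list = []
    for subject, grp in acc_trials.groupby("subject"):
        if per_session:
            fail = any(g["correct"].mean() < min_accuracy
                       for _, g in grp.groupby("session"))
        else:
            fail = grp["correct"].mean() < min_accuracy
        if fail:
            excluded.append(subject)
    if set(excluded) >= set(table.subjects):
        raise ValueError("exclusion criterion removed every subject")
    meta = dict(table.metadata)
    meta["excluded_subjects"] = sorted(map(str, excluded))
    meta["exclusion_min_accuracy"] = min_accuracy
    kept = df[~df["subject"].isin(excluded)].reset_index(drop=True)
    return TrialTable(kept, meta)


def rt_quantiles(rts: Iterable[float], probs: Sequence[float] = DEFAULT_PROBS) -> np.ndarray:
    """RT quantiles by linear interpolation between order statistics (type 7)."""
    x = np.asarray(list(rts), dtype=float)
    if x.size == 0:
        raise ValueError("cannot compute quantiles of an empty sample")
    p = np.asarray(probs, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("quantile probabilities must lie strictly in (0, 1)")
    if np.any(np.diff(p) <= 0):
        raise ValueError("quantile probabilities must be strictly increasing")
    return np.quantile(x, p, method="linear")


def summarize_cell(table: TrialTable, session: str, cue: str, subject=None,
                   probs: Sequence[float] = DEFAULT_PROBS,
                   sparse_min: int = SPARSE_ERROR_MIN) -> QuantileSummary:
    """Defective quantile summary of one (session, cue) cell.

    ``p_correct`` is the proportion correct among responded trials.  When
    the cell holds fewer than ``sparse_min`` error responses the error
    quantiles are flagged sparse (``error_quantiles`` is ``None``) and the
    error mass is treated as a single bin by the fitting routines.
    """
    cell = table.cell(session, cue, subject)
    cell = cell[cell["responded"]] if "responded" in cell.columns else cell
    if len(cell) == 0:
        raise ValueError(f"no responded trials in cell ({session}, {cue})")
    rt_s = cell["rt_ms"].to_numpy(dtype=float) / 1000.0
    correct = cell["correct"].to_numpy(dtype=bool)
    n_c, n_e = int(correct.sum()), int((~correct).sum())
    sparse = n_e < sparse_min
    return QuantileSummary(
        session=session, cue=cue,
        n_trials=len(cell), n_correct=n_c, n_error=n_e,
        p_correct=n_c / len(cell),
        probs=tuple(probs),
        correct_quantiles=rt_quantiles(rt_s[correct], probs) if n_c else
        np.full(len(probs), np.nan),
        error_quantiles=None if sparse else rt_quantiles(rt_s[~correct], probs),
        sparse_errors=sparse,
    )


def summarize_subject_session(table: TrialTable, subject, session: str,
                              probs: Sequence[float] = DEFAULT_PROBS,
                              sparse_min: int = SPARSE_ERROR_MIN) -> dict:
    """Quantile summaries for both cues of one subject's session."""
    return {cue: summarize_cell(table, session, cue, subject, probs, sparse_min)
            for cue in CUES}


def vincentize(summaries: Sequence[QuantileSummary]) -> QuantileSummary:
    """Average per-subject quantile summaries for one cell across subjects.

    Group quantiles are unweighted means across subjects at each probability
    (Vincent averaging); the group proportion correct is the mean of subject
    proportions.  Error quantiles are averaged over the subjects whose error
    counts were not sparse.
    """
    if not summaries:
        raise ValueError("no summaries to vincentize")
    first = summaries[0]
    for s in summaries[1:]:
        if s.probs != first.probs:
            raise ValueError("mismatched probability grids")
        if s.cell != first.cell:
            raise ValueError("summaries come from different cells")
    cq = np.mean([s.correct_quantiles for s in summaries], axis=0)
    with_err = [s for s in summaries if s.error_quantiles is not None]
    eq = np.mean([s.error_quantiles for s in with_err], axis=0) if with_err else None
    return QuantileSummary(
        session=first.session, cue=first.cue,
        n_trials=int(sum(s.n_trials for s in summaries)),
        n_correct=int(sum(s.n_correct for s in summaries)),
        n_error=int(sum(s.n_error for s in summaries)),
        p_correct=float(np.mean([s.p_correct for s in summaries])),
        probs=first.probs,
        correct_quantiles=cq,
        error_quantiles=eq,
        sparse_errors=eq is None,
    )
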