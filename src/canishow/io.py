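"""Reading, validating and writing behavioral-coding tables.

Two plain-text dialects, both one long table with a header row:

* event table — ``pair,session,condition,trial,phase,actor,code,referent,onset,offset``
  (optional ``annotation``), one row per coded behavior occurrence;
* metadata table — ``pair,session,condition,trial,target_box,choice_phase1,
  choice_phase2,dog_retrieved,phase1_duration,phase2_duration``, one row per
  pair x session x trial.

XLSX workbooks (the layout of behavioral-coding exports deposited as
supplementary raw data) are accepted for either table and normalized to the
long table immediately on read.  All times are printed with 2 decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .codes import BOX_REFERENT_CODES, GRID
from .events import (
    BehaviorEvent,
    EventLog,
    EventValidationError,
    TrialContext,
    is_on_grid,
    snap_to_grid,
)

__all__ = [
    "FormatError",
    "ValidationReport",
    "read_event_log",
    "read_metadata",
    "load_dataset",
    "write_event_log",
    "write_metadata",
    "validate_dataset",
]

EVENT_COLUMNS = [
    "pair", "session", "condition", "trial", "phase",
    "actor", "code", "referent", "onset", "offset",
]

METADATA_COLUMNS = [
    "pair", "session", "condition", "trial", "target_box",
    "choice_phase1", "choice_phase2", "dog_retrieved",
    "phase1_duration", "phase2_duration",
]


class FormatError(ValueError):
    """The file does not match the expected table dialect."""


@dataclass
class ValidationReport:
    """Per-log violations and dataset-level design warnings (report-only)."""

    violations: list[str] = field(default_factory=list)
    design_warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        lines = [f"{len(self.violations)} violation(s), "
                 f"{len(self.design_warnings)} design warning(s)"]
        lines += [f"  VIOLATION: {v}" for v in self.violations]
        lines += [f"  WARNING:   {w}" for w in self.design_warnings]
        return "\n".join(lines)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        return pd.read_excel(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def _parse_referent(value) -> int | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        if value in ("", "none", "NA", "nan"):
            return None
    return int(value)


def read_event_log(
    path: str | Path,
    metadata: str | Path | dict[tuple, TrialContext] | None = None,
    *,
    snap: bool = False,
) -> list[EventLog]:
    """Read a long-table event file into :class:`EventLog` objects.

    Logs are grouped by (pair, session, trial, phase) and returned sorted by
    that key.  Rows failing the event invariants raise
    :class:`~canishow.events.EventValidationError` naming the offending row;
    with ``snap=True`` off-grid timestamps are snapped to the nearest 0.20 s
    multiple instead.

    *metadata* may be a metadata-table path, an already-loaded context dict
    (from :func:`read_metadata`), or ``None`` — in which case minimal
    contexts without target/choice information are synthesized from the
    event table's own columns.
    """
    df = _read_table(path)
    if df.empty and list(df.columns) == []:
        return []
    _require_columns(df, EVENT_COLUMNS, path)
    if df.empty:
        return []

    if metadata is None:
        contexts: dict[tuple, TrialContext] = {}
    elif isinstance(metadata, (str, Path)):
        contexts = read_metadata(metadata)
    else:
        contexts = dict(metadata)

    logs: dict[tuple, EventLog] = {}
    for idx, row in df.iterrows():
        onset, offset = float(row["onset"]), float(row["offset"])
        if snap:
            onset, offset = snap_to_grid(onset), snap_to_grid(offset)
        elif not (is_on_grid(onset) and is_on_grid(offset)):
            raise EventValidationError(
                f"{path} row {idx}: time not on {GRID} s grid "
                f"(onset={onset}, offset={offset})"
            )
        try:
            event = BehaviorEvent(
                actor=str(row["actor"]).strip(),
                code=str(row["code"]).strip(),
                referent=_parse_referent(row["referent"]),
                onset=onset,
                offset=offset,
                annotation=(str(row["annotation"]).strip()
                            if "annotation" in df.columns
                            and pd.notna(row.get("annotation")) else None),
            )
        except EventValidationError as exc:
            raise EventValidationError(f"{path} row {idx}: {exc}") from None
        key = (str(row["pair"]), int(row["session"]), int(row["trial"]))
        phase = int(row["phase"])
        log_key = (*key, phase)
        if log_key not in logs:
            ctx = contexts.get(key)
            if ctx is None:
                ctx = TrialContext(
                    pair_id=key[0], session=key[1],
                    condition=str(row["condition"]).strip(), trial=key[2],
                )
            logs[log_key] = EventLog(context=ctx, phase=phase)
        logs[log_key].add(event)
    return [logs[k] for k in sorted(logs)]


def read_metadata(path: str | Path) -> dict[tuple, TrialContext]:
    """Read a metadata table into ``{(pair, session, trial): TrialContext}``."""
    df = _read_table(path)
    _require_columns(df, METADATA_COLUMNS, path)
    contexts: dict[tuple, TrialContext] = {}
    for idx, row in df.iterrows():
        try:
            ctx = TrialContext(
                pair_id=str(row["pair"]),
                session=int(row["session"]),
                condition=str(row["condition"]).strip(),
                trial=int(row["trial"]),
                target_box=_parse_referent(row["target_box"]),
                choice_phase1=(None if pd.isna(row["choice_phase1"])
                               else int(row["choice_phase1"])),
                choice_phase2=(None if pd.isna(row["choice_phase2"])
                               else int(row["choice_phase2"])),
                dog_retrieved=bool(row["dog_retrieved"]),
                phase_durations={1: float(row["phase1_duration"]),
                                 2: float(row["phase2_duration"])},
            )
        except (EventValidationError, ValueError) as exc:
            raise EventValidationError(f"{path} row {idx}: {exc}") from None
        contexts[ctx.key] = ctx
    return contexts


def load_dataset(events_path: str | Path, metadata_path: str | Path,
                 *, snap: bool = False) -> tuple[list[EventLog], dict[tuple, TrialContext]]:
    """Read events + metadata together; every log gets its full context."""
    contexts = read_metadata(metadata_path)
    logs = read_event_log(events_path, contexts, snap=snap)
    return logs, contexts


def events_to_frame(logs: list[EventLog]) -> pd.DataFrame:
    rows = []
    for log in logs:
        c = log.context
        for e in log.events:
            rows.append({
                "pair": c.pair_id, "session": c.session, "condition": c.condition,
                "trial": c.trial, "phase": log.phase, "actor": e.actor,
                "code": e.code,
                "referent": "" if e.referent is None else e.referent,
                "onset": f"{e.onset:.2f}", "offset": f"{e.offset:.2f}",
                "annotation": e.annotation or "",
            })
    return pd.DataFrame(rows, columns=EVENT_COLUMNS + ["annotation"])


def write_event_log(logs: list[EventLog], path: str | Path) -> None:
    """Write logs in the long-table dialect (CSV or TSV by extension)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    events_to_frame(logs).to_csv(path, sep=sep, index=False)


def write_metadata(contexts: dict[tuple, TrialContext] | list[TrialContext],
                   path: str | Path) -> None:
    if isinstance(contexts, dict):
        contexts = [contexts[k] for k in sorted(contexts)]
    rows = []
    for c in contexts:
        rows.append({
            "pair": c.pair_id, "session": c.session, "condition": c.condition,
            "trial": c.trial,
            "target_box": "" if c.target_box is None else c.target_box,
            "choice_phase1": "" if c.choice_phase1 is None else c.choice_phase1,
            "choice_phase2": "" if c.choice_phase2 is None else c.choice_phase2,
            "dog_retrieved": int(c.dog_retrieved),
            "phase1_duration": f"{c.phase_durations.get(1, 60.0):.2f}",
            "phase2_duration": f"{c.phase_durations.get(2, 60.0):.2f}",
        })
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, index=False)


# state events whose identical-code overlap within a log indicates a coding slip
_STATE_CODES = frozenset({"near_box", "gaze_box"}) | {"owner_behavior"}


def validate_dataset(logs: list[EventLog]) -> ValidationReport:
    """Report-only validation of a full dataset.

    Checks per log: events inside the phase window; overlapping identical
    state events of the same code + referent.  Checks at the design level:
    the same box must not be target in two consecutive trials of a session,
    and each box should be target exactly twice per pair (warning, not
    error, as in the study design).
    """
    report = ValidationReport()
    for log in logs:
        label = "pair {} s{} t{} phase {}".format(*log.key)
        dur = log.phase_duration
        for e in log.events:
            if e.offset > dur + 1e-9:
                report.violations.append(
                    f"{label}: event {e.code} [{e.onset:.2f}, {e.offset:.2f}) "
                    f"extends past phase duration {dur:.2f}"
                )
        seen: list[BehaviorEvent] = []
        for e in log.events:
            if e.code not in _STATE_CODES:
                continue
            for prev in seen:
                if (prev.code == e.code and prev.referent == e.referent
                        and prev.overlaps(e)):
                    report.violations.append(
                        f"{label}: overlapping {e.code} events "
                        f"[{prev.onset:.2f},{prev.offset:.2f}) and "
                        f"[{e.onset:.2f},{e.offset:.2f}) with same referent"
                    )
            seen.append(e)

    # design-level checks on the distinct trial contexts
    contexts: dict[tuple, TrialContext] = {}
    for log in logs:
        contexts.setdefault(log.context.key, log.context)
    by_pair_session: dict[tuple, dict[int, TrialContext]] = {}
    for (pair, session, trial), ctx in contexts.items():
        by_pair_session.setdefault((pair, session), {})[trial] = ctx
    targets_per_pair: dict[str, list[int]] = {}
    for (pair, session), trials in sorted(by_pair_session.items()):
        order = sorted(trials)
        for t1, t2 in zip(order, order[1:]):
            a, b = trials[t1].target_box, trials[t2].target_box
            if a is not None and a == b and t2 == t1 + 1:
                report.design_warnings.append(
                    f"pair {pair} session {session}: same box {a} is target in "
                    f"consecutive trials {t1} and {t2} "
                    "(design: same box could not be target in two consecutive trials)"
                )
        for ctx in trials.values():
            if ctx.target_box is not None:
                targets_per_pair.setdefault(pair, []).append(ctx.target_box)
    for pair, targets in sorted(targets_per_pair.items()):
        if len(targets) == 8:
            for box in (1, 2, 3, 4):
                if targets.count(box) != 2:
                    report.design_warnings.append(
                        f"pair {pair}: box {box} is target {targets.count(box)} "
                        "time(s); design requires each box to be target twice"
                    )
    return report
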