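"""CSV schemas and round-trip readers/writers.

Schemas (exact headers, UTF-8, '.' decimal separator):

- kinematics: ``t,x_mm,y_mm,z_mm,qw,qx,qy,qz``
- events: ``t,kind``
- outcomes: ``subject_id,item1..item6,failure_mode,group``
- OPI table: ``subject_id`` + the six metric columns
- score matrix: ``subject_id,item1..item12,gated_from,level,group``
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import SchemaError
from .opi import METRIC_NAMES, OpiVector
from .scoring import FAILURE_MODES, ItemResponseMatrix, VideoOutcome
from .synth import EventStream, KinematicStream

KINEMATICS_COLUMNS = ["t", "x_mm", "y_mm", "z_mm", "qw", "qx", "qy", "qz"]
EVENTS_COLUMNS = ["t", "kind"]
OUTCOMES_COLUMNS = ["subject_id"] + [f"item{i}" for i in range(1, 7)] + ["failure_mode", "group"]
OPI_COLUMNS = ["subject_id"] + list(METRIC_NAMES)
SCORE_COLUMNS = (
    ["subject_id"] + [f"item{i}" for i in range(1, 13)] + ["gated_from", "level", "group"]
)

_FLOAT_FMT = "%.12g"


def _check_header(df: pd.DataFrame, expected: list[str], path: Path) -> None:
    if list(df.columns) != expected:
        raise SchemaError(
            f"{path}: header {list(df.columns)} does not match schema {expected}"
        )


def write_kinematics_csv(stream: KinematicStream, path: str | Path) -> None:
    df = pd.DataFrame(
        np.column_stack([stream.t, stream.pos, stream.quat]), columns=KINEMATICS_COLUMNS
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_kinematics_csv(path: str | Path) -> KinematicStream:
    path = Path(path)
    df = pd.read_csv(path)
    _check_header(df, KINEMATICS_COLUMNS, path)
    t = df["t"].to_numpy(float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        # diff index k compares data rows k and k+1; the offending sample is
        # file row k+3 (1-based, after the header)
        raise SchemaError(f"{path}: non-monotone time at row {bad[0] + 3}, column 't'")
    return KinematicStream(
        t=t,
        pos=df[["x_mm", "y_mm", "z_mm"]].to_numpy(float),
        quat=df[["qw", "qx", "qy", "qz"]].to_numpy(float),
    )


def write_events_csv(events: EventStream, path: str | Path) -> None:
    df = pd.DataFrame(events.events, columns=EVENTS_COLUMNS)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_events_csv(path: str | Path) -> EventStream:
    path = Path(path)
    df = pd.read_csv(path)
    _check_header(df, EVENTS_COLUMNS, path)
    state = 0
    for row, kind in enumerate(df["kind"], start=2):
        if kind == "energy_on":
            if state:
                raise SchemaError(f"{path}: energy_on while energized at row {row}, column 'kind'")
            state = 1
        elif kind == "energy_off":
            if not state:
                raise SchemaError(f"{path}: energy_off before energy_on at row {row}, column 'kind'")
            state = 0
        elif kind != "clutch":
            raise SchemaError(f"{path}: unknown event kind {kind!r} at row {row}, column 'kind'")
    if state:
        raise SchemaError(f"{path}: unterminated energy_on at end of file")
    return EventStream(events=[(float(t), str(k)) for t, k in df.itertuples(index=False)])


def write_outcomes_csv(
    outcomes: Mapping[str, VideoOutcome],
    path: str | Path,
    group: Mapping[str, str] | None = None,
) -> None:
    rows = []
    for sid, vo in outcomes.items():
        row = {"subject_id": sid}
        for i, v in enumerate(vo.item_results, start=1):
            row[f"item{i}"] = v
        row["failure_mode"] = vo.failure_mode
        row["group"] = (group or {}).get(sid, "")
        rows.append(row)
    pd.DataFrame(rows, columns=OUTCOMES_COLUMNS).to_csv(path, index=False)


def read_outcomes_csv(path: str | Path) -> tuple[dict[str, VideoOutcome], dict[str, str]]:
    path = Path(path)
    df = pd.read_csv(path, keep_default_na=False)
    _check_header(df, OUTCOMES_COLUMNS, path)
    outcomes: dict[str, VideoOutcome] = {}
    groups: dict[str, str] = {}
    for idx, row in df.iterrows():
        items = []
        for i in range(1, 7):
            v = row[f"item{i}"]
            if v not in (0, 1, "0", "1"):
                raise SchemaError(
                    f"{path}: non-binary score {v!r} at row {idx + 2}, column 'item{i}'"
                )
            items.append(int(v))
        mode = str(row["failure_mode"])
        if mode not in FAILURE_MODES:
            raise SchemaError(
                f"{path}: unknown failure_mode {mode!r} at row {idx + 2}, column 'failure_mode'"
            )
        sid = str(row["subject_id"])
        outcomes[sid] = VideoOutcome(item_results=tuple(items), failure_mode=mode)
        groups[sid] = str(row["group"])
    return outcomes, groups


def write_opi_csv(opis: Mapping[str, OpiVector], path: str | Path) -> None:
    rows = [{"subject_id": sid, **vec.as_dict()} for sid, vec in opis.items()]
    pd.DataFrame(rows, columns=OPI_COLUMNS).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_opi_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _check_header(df, OPI_COLUMNS, path)
    return df.set_index("subject_id")


def write_score_csv(matrix: ItemResponseMatrix, path: str | Path) -> None:
    rows = []
    for n, sid in enumerate(matrix.subject_ids):
        row = {"subject_id": sid}
        for i in range(matrix.n_items):
            row[f"item{i + 1}"] = int(matrix.scores[n, i])
        row["gated_from"] = int(matrix.gated_from[n])
        row["level"] = matrix.levels[n] if matrix.levels else ""
        row["group"] = matrix.group[n] if matrix.group else ""
        rows.append(row)
    pd.DataFrame(rows, columns=SCORE_COLUMNS).to_csv(path, index=False)


def read_score_csv(path: str | Path) -> ItemResponseMatrix:
    path = Path(path)
    df = pd.read_csv(path, keep_default_na=False)
    _check_header(df, SCORE_COLUMNS, path)
    item_cols = [f"item{i}" for i in range(1, 13)]
    for col in item_cols:
        bad = ~df[col].isin([0, 1, "0", "1"])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise SchemaError(
                f"{path}: non-binary score {df[col][bad.idxmax()]!r} at row {row}, column '{col}'"
            )
    return ItemResponseMatrix(
        subject_ids=[str(s) for s in df["subject_id"]],
        scores=df[item_cols].to_numpy(int),
        gated_from=df["gated_from"].to_numpy(int),
        group=[str(g) for g in df["group"]],
        levels=[str(lv) for lv in df["level"]],
    )
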