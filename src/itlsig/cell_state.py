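"""Two-axis GBM cell-state geometry.

Each cell carries four consolidated module scores (MES, AC, OPC, NPC). The
vertical coordinate is

    y = max(SC_opc, SC_npc) - max(SC_ac, SC_mes)

so y > 0 places the cell in the OPC/NPC lineage and y <= 0 in AC/MES (the
y = 0 tie resolves to AC/MES). Within the assigned lineage the horizontal
magnitude is log2(|pair difference| + 1); under the default "neftel" sign
convention x is negative when the pair's first member (OPC or AC) dominates
and positive when the second (NPC or MES) does, reproducing the familiar
four-quadrant state plot. The discrete state label is the argmax of the four
scores with the fixed tie priority MES > AC > OPC > NPC.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ModuleScores
from .exceptions import ValidationError

STATE_COLUMNS = ("MES", "AC", "OPC", "NPC")
#: argmax tie priority, highest first
STATE_PRIORITY = ("MES", "AC", "OPC", "NPC")


def _as_frame(scores: ModuleScores | pd.DataFrame) -> pd.DataFrame:
    df = scores.scores if isinstance(scores, ModuleScores) else scores
    for col in STATE_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"missing consolidated score column {col!r}")
    if not np.all(np.isfinite(df[list(STATE_COLUMNS)].to_numpy(dtype=float))):
        raise ValidationError("state scores must be finite")
    return df


def assign_state(scores: ModuleScores | pd.DataFrame) -> pd.Series:
    """Discrete state per cell: argmax of the four consolidated scores,
    ties resolved by the fixed priority MES > AC > OPC > NPC."""
    df = _as_frame(scores)
    mat = df[list(STATE_PRIORITY)].to_numpy(dtype=float)
    # np.argmax returns the first maximum, which is the priority order.
    idx = np.argmax(mat, axis=1)
    return pd.Series(
        [STATE_PRIORITY[i] for i in idx], index=df.index, name="state"
    )


def state_coordinates(
    scores: ModuleScores | pd.DataFrame, x_sign: str = "neftel"
) -> pd.DataFrame:
    """Per-cell plot coordinates, lineage and state.

    ``x_sign`` is "neftel" (sign by within-pair winner, the default) or
    "magnitude" (x reported unsigned, as printed in the source formulas).
    Returns a DataFrame with columns MES, AC, OPC, NPC, x, y, lineage, state.
    """
    if x_sign not in ("neftel", "magnitude"):
        raise ValidationError(f"unknown x sign convention {x_sign!r}")
    df = _as_frame(scores)
    mes = df["MES"].to_numpy(dtype=float)
    ac = df["AC"].to_numpy(dtype=float)
    opc = df["OPC"].to_numpy(dtype=float)
    npc = df["NPC"].to_numpy(dtype=float)

    y = np.maximum(opc, npc) - np.maximum(ac, mes)
    opc_npc = y > 0
    lineage = np.where(opc_npc, "OPC/NPC", "AC/MES")
    pair_diff = np.where(opc_npc, opc - npc, ac - mes)
    x = np.log2(np.abs(pair_diff) + 1.0)
    if x_sign == "neftel":
        # first pair member (OPC or AC) dominating -> negative x
        x = np.where(pair_diff > 0, -x, x)

    out = df[list(STATE_COLUMNS)].copy()
    out["x"] = x
    out["y"] = y
    out["lineage"] = lineage
    out["state"] = assign_state(df)
    out.index.name = "cell_id"
    return out


def state_signature_correlation(
    scores: ModuleScores | pd.DataFrame, extra: pd.Series
) -> pd.DataFrame:
    """Pearson correlation of an extra per-cell variable (a score or a gene's
    expression) against each of the four state scores.

    Returns a DataFrame indexed by state with columns ``r``, ``p`` and
    ``defined``; a zero-variance input yields r = NaN flagged undefined
    rather than a silent zero.
    """
    df = _as_frame(scores)
    aligned = extra.reindex(df.index)
    if aligned.isna().any():
        raise ValidationError("extra variable does not cover every cell")
    if len(df) < 3:
        raise ValidationError("need at least 3 cells for correlation")
    rows = []
    x = aligned.to_numpy(dtype=float)
    for col in STATE_COLUMNS:
        yv = df[col].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(yv) == 0:
            rows.append((col, np.nan, np.nan, False))
            continue
        r, p = stats.pearsonr(x, yv)
        rows.append((col, float(r), float(p), True))
    return pd.DataFrame(
        rows, columns=["state", "r", "p", "defined"]
    ).set_index("state")
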