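"""Treatment-history output: history.csv and summary.json.

Column order and JSON field order are fixed so repeated runs with the same
configuration and seed produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .protocol import CycleRecord, TreatmentHistory

__all__ = ["HISTORY_COLUMNS", "write_history", "read_history"]

HISTORY_COLUMNS = [
    "cycle", "t_month", "dose", "tumor_radius_m",
    "n_before", "fkc_tumor", "n_after_kill", "regrow_months",
    "n_after_regrow", "s_f", "growth_factor",
    "fkc_normal", "healthy_before", "healthy_after_kill", "healthy_after_regrow",
    "kill_pp", "regrowth_pp", "survival_pct", "side_effect_pct",
]


def write_history(history: TreatmentHistory, outdir) -> dict[str, Path]:
    """Write ``history.csv`` and ``summary.json`` into ``outdir``."""
    if not history.cycles:
        raise ValueError("refusing to write an empty treatment history")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = history.to_frame()[HISTORY_COLUMNS]
    csv_path = outdir / "history.csv"
    df.to_csv(csv_path, index=False, float_format="%.12g", lineterminator="\n")
    summary_path = outdir / "summary.json"
    with open(summary_path, "w") as f:
        json.dump(history.summary(), f, indent=2, sort_keys=False)
        f.write("\n")
    return {"history": csv_path, "summary": summary_path}


def read_history(path) -> pd.DataFrame:
    """Read a ``history.csv`` back into a DataFrame."""
    return pd.read_csv(path)
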