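"""TSV serialisation and run manifests.

All tabular output is tab-separated UTF-8 with '.' decimals and a header
row; each run directory carries a plain-text manifest recording package
version, configuration hash, tolerances and column units.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__

__all__ = ["write_tsv", "write_manifest", "events_table", "metrics_table"]

UNITS = {
    "time_min": "min", "T_div": "min", "T_G1": "min", "T_SG2M": "min",
    "t": "min", "t_peak": "min", "S_phase": "min per ln-unit",
    "Z_phase": "dimensionless", "volume": "arbitrary (fL-like)",
    "V_div": "arbitrary (fL-like)", "V_bud": "arbitrary (fL-like)",
    "V_dau": "arbitrary (fL-like)", "f": "dimensionless",
    "C": "observable units per ln-unit of parameter",
    "S": "observable units per ln-unit of parameter",
    "Z": "observable units per ln-unit per min",
    "B": "dimensionless (0..1)",
}


def write_tsv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    return path


def write_manifest(out_dir: str | Path, config_dict: dict, extra: dict | None = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    lines = [
        f"cyclesens version\t{__version__}",
        f"config sha256\t{hashlib.sha256(blob).hexdigest()}",
    ]
    for k, v in (extra or {}).items():
        lines.append(f"{k}\t{v}")
    lines.append("")
    lines.append("column units:")
    for col, unit in UNITS.items():
        lines.append(f"  {col}\t{unit}")
    path = out_dir / "manifest.txt"
    path.write_text("\n".join(lines) + "\n")
    return path


def events_table(traj) -> pd.DataFrame:
    """Event stream as a stable-column-order table."""
    return pd.DataFrame(
        [
            {"generation": e.generation, "event": e.kind,
             "time_min": e.time, "volume": e.volume}
            for e in traj.events
        ],
        columns=["generation", "event", "time_min", "volume"],
    )


def metrics_table(metrics_list) -> pd.DataFrame:
    rows = []
    for i, m in enumerate(metrics_list, start=1):
        row = {"generation": i}
        row.update(m.as_dict())
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["generation", "T_div", "T_G1", "T_SG2M", "V_div", "V_bud", "V_dau", "f"],
    )
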