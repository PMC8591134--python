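"""Reading and writing of the tabular record streams.

Reports travel as JSON-Lines (one report object per line); treatment and
clinical events, candidates, cases and truth as plain CSV.  All dates are
ISO-8601 strings on disk and parsed to timestamps on read where needed.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = ["write_streams", "read_reports", "read_csv", "write_reports"]

REPORT_COLUMNS = ["patient_id", "report_id", "scan_date", "request_text", "body_text"]


def write_reports(reports: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for _, row in reports.iterrows():
            fh.write(json.dumps({c: row[c] for c in REPORT_COLUMNS}) + "\n")


def read_reports(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                rows.append(json.loads(line))
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False, na_values=[""])


def write_streams(streams: dict[str, pd.DataFrame], out_dir: str | Path) -> dict[str, Path]:
    """Write the generator's streams to their canonical file names."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in streams.items():
        if name == "reports":
            paths[name] = out / "reports.jsonl"
            write_reports(df, paths[name])
        else:
            paths[name] = out / f"{name}.csv"
            df.to_csv(paths[name], index=False)
    return paths
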