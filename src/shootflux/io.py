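"""Readers for the raw campaign file set (and external column mappings).

The native dialect (version 1) is what :func:`shootflux.synthetic.write_campaign`
emits: per-closure analyser CSVs with iso-8601 timestamps plus campaign-level
``closures.csv``, ``meteo.csv`` and ``biomass.csv``.  ``COLUMN_MAP`` can be
overridden to ingest externally deposited analyser files whose headers
differ; values are the native names, keys the foreign ones.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .closures import ClosureSeries

#: foreign-header -> native-header translation applied before parsing
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "Time": "timestamp",
    "[CH4]d_ppm": "ch4_dry_ppm",
    "[CO2]_ppm": "co2_ppm",
    "[H2O]_ppm": "h2o_ppm",
    "GasT_C": "sample_temp_K",
}

ANALYZER_COLUMNS = ["timestamp", "ch4_dry_ppm", "co2_ppm", "h2o_ppm", "sample_temp_K"]


def read_analyzer_csv(
    path: str | Path, column_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """One closure's analyser record with ``t`` in seconds since its start."""
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in ANALYZER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: analyzer file missing columns {missing}")
    ts = pd.to_datetime(df["timestamp"])
    out = pd.DataFrame(
        {
            "t": (ts - ts.iloc[0]).dt.total_seconds(),
            "ch4_dry_raw": df["ch4_dry_ppm"].astype(float),
            "co2": df["co2_ppm"].astype(float),
            "h2o": df["h2o_ppm"].astype(float),
            "sample_temp": df["sample_temp_K"].astype(float),
        }
    )
    out.attrs["start_time"] = ts.iloc[0]
    return out


def read_campaign_dir(
    root: str | Path, column_map: dict[str, str] | None = None
) -> dict:
    """Load a raw campaign directory into closures + meteo + biomass frames."""
    root = Path(root)
    meta = pd.read_csv(root / "closures.csv", parse_dates=["start_time", "end_time"])
    meteo = pd.read_csv(root / "meteo.csv", parse_dates=["timestamp"])
    biomass = pd.read_csv(root / "biomass.csv")
    closures = []
    for row in meta.itertuples():
        f = root / "raw" / f"{row.closure_id}.csv"
        if not f.exists():
            raise FileNotFoundError(f"analyzer file for closure {row.closure_id}: {f}")
        data = read_analyzer_csv(f, column_map)
        closures.append(
            ClosureSeries(
                chamber_id=row.chamber_id,
                shoot_id=row.shoot_id,
                species=row.species,
                data=data,
                closure_id=row.closure_id,
                start_time=row.start_time,
            )
        )
    return {"closures": closures, "metadata": meta, "meteo": meteo, "biomass": biomass}
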