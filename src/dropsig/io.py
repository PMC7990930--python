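"""Input/output plumbing: droplet CSV ingestion and the end-to-end run.

The package consumes the tabular export of upstream image analysis
(CellProfiler-style): one row per droplet with an area column and one
mean-intensity column per fluorescence channel.  Column names are bound
through :class:`ColumnBindings`; the defaults match the CellProfiler
export convention (``AreaShape_Area``,
``Intensity_MeanIntensity_<channel>``).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import ClusteringSpec, DropletClassifier
from .deconvolve import deconvolve_pipeline
from .signatures import MarkerPanel, SignatureProfile, DEFAULT_PANEL

__all__ = ["ColumnBindings", "RunConfig", "read_droplet_csv", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ColumnBindings:
    """Binding of logical fields to CSV columns."""

    area: str = "AreaShape_Area"
    intensity_prefix: str = "Intensity_MeanIntensity_"
    channels: Mapping[str, str] | None = None  # channel name -> explicit column

    def column_for(self, channel: str) -> str:
        if self.channels and channel in self.channels:
            return self.channels[channel]
        return f"{self.intensity_prefix}{channel}"


def read_droplet_csv(path, bindings: ColumnBindings | None = None,
                     channels: Sequence[str] = ()) -> pd.DataFrame:
    """Read a droplet measurement CSV into the internal table layout.

    Returns a frame with columns ``area`` plus one column per channel
    (logical names).  Rows with missing or non-numeric bound fields are
    dropped with a logged count; a missing bound column is an error.
    """
    bindings = bindings or ColumnBindings()
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"droplet CSV {path} contains no rows")
    wanted = {"area": bindings.area}
    for ch in channels:
        wanted[ch] = bindings.column_for(ch)
    missing = [col for col in wanted.values() if col not in df.columns]
    if missing:
        raise ValueError(f"droplet CSV {path} is missing columns: {missing}")
    out = pd.DataFrame({name: pd.to_numeric(df[col], errors="coerce")
                        for name, col in wanted.items()})
    bad = out.isna().any(axis=1)
    if bad.any():
        logger.info("dropping %d rows with missing/non-numeric fields", int(bad.sum()))
        out = out.loc[~bad]
    if out.empty:
        raise ValueError(f"droplet CSV {path} has no valid rows after cleaning")
    return out.reset_index(drop=True)


@dataclass
class RunConfig:
    """Configuration of an end-to-end classify -> deconvolve run."""

    panel: MarkerPanel = field(default_factory=lambda: DEFAULT_PANEL)
    bindings: ColumnBindings = field(default_factory=ColumnBindings)
    min_area: float = 0.0
    max_area: float = math.inf
    specs: Mapping[str, ClusteringSpec] | None = None
    default_spec: ClusteringSpec | None = None
    reference_paths: Sequence[str] = ()
    references: Sequence[SignatureProfile] | None = None
    variant: str = "verbatim"
    step2: bool = True
    tol: float = 1e-10
    max_iter: int = 10_000

    def load_references(self) -> list[SignatureProfile]:
        if self.references is not None:
            return list(self.references)
        if not self.reference_paths:
            raise ValueError("run config names no reference profiles")
        return [SignatureProfile.from_csv(p, role="reference", renormalize=True)
                for p in self.reference_paths]


def run_pipeline(input_csv, config: RunConfig, output_json=None) -> dict:
    """Execute Step 1 (classify) then Steps 2-3 (deconvolve) on one CSV.

    Returns the result bundle; optionally writes it as JSON (all
    probabilities at full precision).
    """
    channels = [config.panel.cell_channel] + config.panel.marker_channels()
    table = read_droplet_csv(input_csv, config.bindings, channels)
    table = table.rename(columns={"area": "area"})

    clf = DropletClassifier(panel=config.panel, min_area=config.min_area,
                            max_area=config.max_area, area_column="area",
                            specs=config.specs, default_spec=config.default_spec)
    clf.fit(table)
    references = config.load_references()
    dec = deconvolve_pipeline(clf.result_, references, variant=config.variant,
                              tol=config.tol, max_iter=config.max_iter,
                              step2=config.step2)
    bundle = {
        "classified": clf.result_.summary(),
        "s": list(map(float, dec["s"])),
        "w": list(map(float, dec["mixture"].weights)),
        "raw_w": list(map(float, dec["mixture"].raw_weights)),
        "residual": dec["mixture"].residual,
        "diagnostics": dec["diagnostics"],
    }
    if output_json is not None:
        Path(output_json).write_text(json.dumps(bundle, indent=2))
    return bundle
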