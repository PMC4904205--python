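"""CSV input/output for curves and fit reports.

The interchange format is a long-format CSV with the header
``species_id,replicate_id,irradiance,a_net`` — one row per measured point,
curves identified by the (species, replicate) pair.  Reports are plain CSV
with a fixed column order, preceded by ``#``-comment lines embedding the
configuration and master seed needed to regenerate them.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .pipeline import LightResponseDataset
from .synthgen import SyntheticCurve

__all__ = [
    "DataFormatError",
    "read_datasets",
    "read_report",
    "write_datasets",
    "write_report",
    "write_truth",
]

log = logging.getLogger("lightresponse")

REQUIRED_COLUMNS = ["species_id", "replicate_id", "irradiance", "a_net"]


class DataFormatError(ValueError):
    """Raised for malformed input files (missing headers, empty input)."""


def read_datasets(path) -> list[LightResponseDataset]:
    """Read light-response curves from a long-format CSV.

    Rows with non-numeric or negative irradiance, or non-numeric a_net, are
    dropped with a logged warning naming the offending line; a missing
    required column or an empty file raises :class:`DataFormatError`.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise DataFormatError(f"{path}: empty input file") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise DataFormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    if frame.empty:
        raise DataFormatError(f"{path}: no data rows")

    irr = pd.to_numeric(frame["irradiance"], errors="coerce")
    an = pd.to_numeric(frame["a_net"], errors="coerce")
    bad = irr.isna() | an.isna() | (irr < 0)
    for i in frame.index[bad]:
        # +2: one for the header, one for 1-based line numbering
        log.warning("%s: dropping malformed row at line %d: %s", path, i + 2,
                    frame.loc[i].to_dict())
    frame = frame.loc[~bad]
    frame = frame.assign(irradiance=irr[~bad], a_net=an[~bad])

    datasets = []
    for (species, rep), group in frame.groupby(["species_id", "replicate_id"], sort=False):
        datasets.append(
            LightResponseDataset(
                species_id=str(species),
                replicate_id=str(rep),
                irradiance=group["irradiance"].to_numpy(),
                a_net=group["a_net"].to_numpy(),
            )
        )
    if not datasets:
        raise DataFormatError(f"{path}: no valid data rows")
    return datasets


def write_datasets(datasets: Iterable[LightResponseDataset], path,
                   metadata: Optional[Mapping] = None) -> None:
    """Write curves to the long-format CSV, optionally with metadata comments."""
    rows = []
    for ds in datasets:
        for I, A in zip(ds.irradiance, ds.a_net):
            rows.append({"species_id": ds.species_id, "replicate_id": ds.replicate_id,
                         "irradiance": I, "a_net": A})
    _write_with_header(pd.DataFrame(rows, columns=REQUIRED_COLUMNS), path, metadata)


def write_truth(curves: Iterable[SyntheticCurve], path,
                metadata: Optional[Mapping] = None) -> None:
    """Sidecar CSV of generating truths for a synthetic suite."""
    from .models import get_model

    rows = []
    for c in curves:
        row = {"species_id": c.dataset.species_id, "replicate_id": c.dataset.replicate_id,
               "model": c.model, "noise_sd": c.noise_sd}
        for name, value in zip(get_model(c.model).param_names, c.true_params):
            row[name] = value
        rows.append(row)
    cols = ["species_id", "replicate_id", "model", "noise_sd",
            "a", "amax", "rd", "theta", "beta", "gamma"]
    frame = pd.DataFrame(rows).reindex(columns=cols)
    _write_with_header(frame, path, metadata)


def write_report(table: pd.DataFrame, path, metadata: Optional[Mapping] = None) -> None:
    """Write a fit/benchmark report CSV with embedded provenance comments."""
    if table.empty:
        raise ValueError("refusing to write an empty report")
    _write_with_header(table, path, metadata)


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _write_with_header(frame: pd.DataFrame, path, metadata: Optional[Mapping]) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if metadata:
            for key, value in metadata.items():
                fh.write(f"# {key}={value}\n")
        frame.to_csv(fh, index=False)
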