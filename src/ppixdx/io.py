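"""Node acquisition I/O: multi-page TIFF + JSON sidecar.

One node is stored as an uncompressed multi-page float32 TIFF (page 0 is the
binary node mask, the remaining pages the band images in a deterministic
order: sorted by excitation, center wavelength, then phase) plus a JSON
sidecar with canonical key order carrying all metadata, so a rewrite of an
unchanged record is byte-identical.  A cohort is a directory of node pairs
plus a ``truth.csv`` ground-truth table.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import tifffile

from .bands import BandImage, FilterBand, NodeRecord, Phase
from .exceptions import NodeIOError, ValidationError

_PHASE_ORDER = {Phase.PRE: 0, Phase.POST: 1}
SIDECAR_SUFFIX = ".json"
TIFF_SUFFIX = ".tif"
TRUTH_CSV = "truth.csv"


def _sorted_keys(record: NodeRecord) -> list[tuple[FilterBand, Phase]]:
    return sorted(
        record.images,
        key=lambda k: (k[0].excitation, k[0].center_wavelength, _PHASE_ORDER[k[1]]),
    )


def write_node(record: NodeRecord, tiff_path, sidecar_path) -> None:
    """Write a node record; deterministic page order and byte-stable sidecar."""
    record.validate()
    keys = _sorted_keys(record)
    pages = [record.mask.astype(np.float32)]
    meta = []
    for page_idx, (band, phase) in enumerate(keys, start=1):
        img = record.images[(band, phase)]
        pages.append(img.pixels.astype(np.float32))
        meta.append(
            {
                "page": page_idx,
                "excitation_nm": band.excitation,
                "center_nm": band.center_wavelength,
                "fwhm_nm": band.fwhm,
                "phase": phase.value,
                "cumulative_fluence_j_cm2": img.cumulative_fluence,
            }
        )
    sidecar = {
        "node_id": record.node_id,
        "pixel_size_mm": record.pixel_size,
        "label": record.label,
        "shape": list(record.mask.shape),
        "mask_page": 0,
        "pages": meta,
    }
    tiff_path, sidecar_path = Path(tiff_path), Path(sidecar_path)
    try:
        tifffile.imwrite(tiff_path, np.stack(pages), compression=None)
        sidecar_path.write_text(
            json.dumps(sidecar, sort_keys=True, indent=1, separators=(",", ": "))
            + "\n"
        )
    except OSError as exc:
        raise NodeIOError(f"cannot write node {record.node_id}: {exc}") from exc


def read_node(tiff_path, sidecar_path) -> NodeRecord:
    """Read a node record back; round-trips :func:`write_node` pixel-exactly."""
    tiff_path, sidecar_path = Path(tiff_path), Path(sidecar_path)
    try:
        sidecar = json.loads(Path(sidecar_path).read_text())
        pages = tifffile.imread(tiff_path)
    except OSError as exc:
        raise NodeIOError(f"cannot read node files: {exc}") from exc
    if pages.ndim == 2:
        pages = pages[None]
    n_pages = pages.shape[0]
    n_expected = len(sidecar["pages"]) + 1  # + mask page
    if n_pages != n_expected:
        raise ValidationError(
            f"sidecar {sidecar_path.name} lists {n_expected} pages "
            f"(incl. mask) but TIFF has {n_pages}"
        )
    mask = pages[sidecar["mask_page"]] > 0.5
    pixel_size = float(sidecar["pixel_size_mm"])
    images = {}
    for m in sidecar["pages"]:
        band = FilterBand(
            excitation=float(m["excitation_nm"]),
            center_wavelength=float(m["center_nm"]),
            fwhm=float(m["fwhm_nm"]),
        )
        phase = Phase(m["phase"])
        images[(band, phase)] = BandImage(
            pixels=pages[m["page"]],
            band=band,
            cumulative_fluence=float(m["cumulative_fluence_j_cm2"]),
            pixel_size=pixel_size,
            phase=phase,
        )
    return NodeRecord(
        node_id=sidecar["node_id"],
        mask=mask,
        pixel_size=pixel_size,
        images=images,
        label=sidecar["label"],
    )


def node_paths(directory, node_id: str) -> tuple[Path, Path]:
    d = Path(directory)
    return d / f"{node_id}{TIFF_SUFFIX}", d / f"{node_id}{SIDECAR_SUFFIX}"


def write_cohort(
    records_with_truth: Iterable[tuple[NodeRecord, dict]], directory
) -> pd.DataFrame:
    """Write nodes plus the ground-truth CSV; returns the truth table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for record, row in records_with_truth:
        tiff, sidecar = node_paths(directory, record.node_id)
        write_node(record, tiff, sidecar)
        rows.append(row)
    truth = pd.DataFrame(rows)
    truth.to_csv(directory / TRUTH_CSV, index=False)
    return truth


def iter_cohort_dir(directory) -> Iterator[NodeRecord]:
    """Yield node records from a cohort directory in node-id order."""
    directory = Path(directory)
    tiffs = sorted(directory.glob(f"*{TIFF_SUFFIX}"))
    if not tiffs:
        raise NodeIOError(f"no node TIFFs found in {directory}")
    for tiff in tiffs:
        yield read_node(tiff, tiff.with_suffix(SIDECAR_SUFFIX))


def read_truth(directory) -> pd.DataFrame:
    path = Path(directory) / TRUTH_CSV
    try:
        return pd.read_csv(path)
    except OSError as exc:
        raise NodeIOError(f"cannot read truth table {path}: {exc}") from exc
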