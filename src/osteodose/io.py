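"""Readers and writers: raw phantom + JSON sidecar, MCNP lattices, results.

The phantom interchange format is a raw little-endian unsigned-byte 3-D
array (C order, x index slowest) next to a JSON sidecar holding dimensions,
resolution, origin, the label legend, seeds and the segment parameters, so a
phantom can be reconstructed without the generating session.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .registry import MicroSpec, SegmentSpec
from .transport import TallyResult
from .voxelizer import LABEL_LEGEND, VoxelPhantom


def write_phantom(ph: VoxelPhantom, basepath) -> tuple[Path, Path]:
    """Write ``<base>.raw`` + ``<base>.json``; returns the two paths."""
    base = Path(basepath)
    raw = base.with_suffix(".raw")
    sidecar = base.with_suffix(".json")
    ph.labels.astype(np.uint8).tofile(raw)
    meta = {
        "format": "osteodose-phantom-v1",
        "shape": list(ph.labels.shape),
        "order": "C",
        "dtype": "uint8",
        "resolution_um": ph.resolution_um,
        "origin_cm": [float(v) for v in ph.origin],
        "label_legend": {str(k): v for k, v in LABEL_LEGEND.items()},
        "seed": ph.seed,
        "spacing_scale": ph.spacing_scale,
        "spec_hash": ph.spec_hash(),
        "segment": _spec_dict(ph.segment),
        "micro": _micro_dict(ph.micro) if ph.micro is not None else None,
    }
    sidecar.write_text(json.dumps(meta, indent=1))
    return raw, sidecar


def _spec_dict(spec: SegmentSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["capped_faces"] = list(spec.capped_faces)
    return d


def _micro_dict(micro: MicroSpec) -> dict:
    return dataclasses.asdict(micro)


def read_phantom(basepath) -> VoxelPhantom:
    base = Path(basepath)
    meta = json.loads(base.with_suffix(".json").read_text())
    if meta.get("format") != "osteodose-phantom-v1":
        raise ValueError(f"not an osteodose phantom sidecar: {base}")
    labels = np.fromfile(base.with_suffix(".raw"), dtype=np.uint8).reshape(meta["shape"])
    seg = meta["segment"]
    seg["capped_faces"] = tuple(seg["capped_faces"])
    spec = SegmentSpec(**seg)
    micro = MicroSpec(**meta["micro"]) if meta.get("micro") else None
    return VoxelPhantom(
        labels=labels,
        resolution_um=meta["resolution_um"],
        origin=np.array(meta["origin_cm"]),
        segment=spec,
        micro=micro,
        seed=meta["seed"],
        spacing_scale=meta.get("spacing_scale", 1.0),
    )


# ---------------------------------------------------------------------------
# MCNP-style lattice output


def _fill_values(arr: np.ndarray) -> np.ndarray:
    # MCNP fill arrays run the first lattice index fastest
    return arr.ravel(order="F")


def _compress(values: np.ndarray) -> list[str]:
    """MCNP repeat syntax: ``v nR`` repeats the previous entry n more times."""
    out: list[str] = []
    run_val = int(values[0])
    run_len = 1
    for v in values[1:]:
        v = int(v)
        if v == run_val:
            run_len += 1
        else:
            out.append(str(run_val) if run_len == 1 else f"{run_val} {run_len - 1}R")
            run_val, run_len = v, 1
    out.append(str(run_val) if run_len == 1 else f"{run_val} {run_len - 1}R")
    return out


def _write_lattice(arr: np.ndarray, resolution_um: float, path: Path, title: str) -> None:
    nx, ny, nz = arr.shape
    tokens = _compress(_fill_values(arr))
    lines = [
        f"c {title}",
        f"c voxel lattice {nx} x {ny} x {nz}, pitch {resolution_um:.1f} um, LAT=1",
        "c universes: 0 void, 1 cortical bone, 2 trabecular bone, 3 marrow",
        f"fill=0:{nx - 1} 0:{ny - 1} 0:{nz - 1}",
    ]
    line = "     "
    for tok in tokens:
        if len(line) + len(tok) + 1 > 78:
            lines.append(line)
            line = "     "
        line += " " + tok
    lines.append(line)
    path.write_text("\n".join(lines) + "\n")


def write_mcnp_lattice(ph: VoxelPhantom, basepath) -> tuple[Path, Path, Path]:
    """Write the phantom lattice plus TBV-only and CBV-only source masks.

    Three text files are produced: ``<base>_phantom.txt`` with all four
    labels as universe numbers, and ``<base>_tbv.txt`` / ``<base>_cbv.txt``
    masks holding 1 inside the respective source region and 0 elsewhere.
    """
    base = Path(basepath)
    p_full = base.parent / f"{base.name}_phantom.txt"
    p_tbv = base.parent / f"{base.name}_tbv.txt"
    p_cbv = base.parent / f"{base.name}_cbv.txt"
    _write_lattice(ph.labels, ph.resolution_um, p_full, "whole computational phantom")
    _write_lattice(
        (ph.labels == 2).astype(np.uint8), ph.resolution_um, p_tbv, "TBV source mask"
    )
    _write_lattice(
        (ph.labels == 1).astype(np.uint8), ph.resolution_um, p_cbv, "CBV source mask"
    )
    return p_full, p_tbv, p_cbv


def read_mcnp_lattice(path) -> np.ndarray:
    """Parse one of our lattice files back into a 3-D array (round-trip check)."""
    text = Path(path).read_text().splitlines()
    dims = None
    values: list[int] = []
    for line in text:
        s = line.strip()
        if s.startswith("c ") or not s:
            continue
        if s.startswith("fill="):
            spans = s[len("fill=") :].split()
            dims = [int(sp.split(":")[1]) + 1 for sp in spans]
            continue
        for tok in s.split():
            if tok.endswith("R"):
                values.extend([values[-1]] * int(tok[:-1]))
            else:
                values.append(int(tok))
    if dims is None:
        raise ValueError(f"no fill= card in {path}")
    arr = np.array(values, dtype=np.uint8)
    return arr.reshape(dims, order="F")


# ---------------------------------------------------------------------------
# tallies and DF tables


def write_tally(tally: TallyResult, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(dataclasses.asdict(tally), indent=1))
    return path


def read_tally(path) -> TallyResult:
    return TallyResult(**json.loads(Path(path).read_text()))


def _round_sig(x: float, sig: int = 2) -> float:
    if x == 0 or not np.isfinite(x):
        return x
    return float(np.format_float_positional(x, precision=sig, fractional=False))


def write_df_csv(table: pd.DataFrame, basepath, config_hash: str = "") -> tuple[Path, Path]:
    """Write the DF report (2 significant figures, table style) plus a
    full-precision machine-readable sidecar CSV."""
    base = Path(basepath)
    report = base.with_suffix(".csv")
    sidecar = base.parent / f"{base.stem}_full.csv"
    rounded = table.copy()
    for col in rounded.columns:
        if col.startswith(("DF_", "SE_")):
            rounded[col] = rounded[col].map(lambda v: _round_sig(v, 2))
        elif col.startswith("CV_"):
            rounded[col] = rounded[col].map(
                lambda v: None if v is None or pd.isna(v) else round(float(v))
            )
    header = f"# osteodose dose-factor table, units 1e-14 Gy/s per Bq/kg; config {config_hash}\n"
    report.write_text(header + rounded.to_csv(index=False))
    sidecar.write_text(header + table.to_csv(index=False))
    return report, sidecar
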