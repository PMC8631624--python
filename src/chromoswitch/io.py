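"""Readers and writers for maps, tracks, trajectories and landscapes.

Text formats: contact maps as dense whitespace TSV with a one-line header
``#chrom start end resolution``; gene tracks as 4-column BED-like TSV.
Binary containers use NumPy ``.npz`` (compressed) and round-trip bitwise.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .dynamics import Trajectory
from .maps import ContactMap, GeneDensityTrack
from .maxent import FitReport, Landscape
from .polymer import Conformation, PolymerParams
from .segments import SegmentSpec


class FormatError(ValueError):
    """A file does not parse as the expected format."""


# ---------------------------------------------------------------------------
# contact maps
# ---------------------------------------------------------------------------

def write_contact_map(cmap: ContactMap, path) -> None:
    """Write a contact map as TSV (``.tsv``/``.txt``) or npz (``.npz``)."""
    path = Path(path)
    seg = cmap.segment
    if path.suffix == ".npz":
        np.savez_compressed(
            path, probs=cmap.probs, chrom=np.array(seg.chrom_label),
            start_bp=seg.start_bp, end_bp=seg.end_bp,
            resolution_bp=seg.resolution_bp)
        return
    header = f"#{seg.chrom_label}\t{seg.start_bp}\t{seg.end_bp}\t{seg.resolution_bp}\n"
    with open(path, "w") as fh:
        fh.write(header)
        for row in cmap.probs:
            fh.write("\t".join(format(v, ".17g") for v in row) + "\n")


def _symmetrize_checked(p: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    asym = np.abs(p - p.T)
    worst = np.unravel_index(np.argmax(asym), asym.shape)
    if asym[worst] > tol:
        raise FormatError(
            f"matrix asymmetry {asym[worst]:.3g} at (i, j) = "
            f"({int(worst[0])}, {int(worst[1])}) exceeds tolerance {tol}")
    return 0.5 * (p + p.T)


def read_contact_map(path) -> ContactMap:
    """Read a TSV or npz contact map; small asymmetries (< 1e-6) are
    averaged out, larger ones raise a :class:`FormatError`."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as z:
            seg = SegmentSpec(str(z["chrom"]), int(z["start_bp"]),
                              int(z["end_bp"]), int(z["resolution_bp"]))
            probs = z["probs"]
    else:
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith("#"):
                raise FormatError("missing '#chrom start end resolution' header")
            fields = header[1:].split()
            if len(fields) != 4:
                raise FormatError(f"malformed header: {header!r}")
            seg = SegmentSpec(fields[0], int(fields[1]), int(fields[2]),
                              int(fields[3]))
            try:
                probs = np.loadtxt(fh, ndmin=2)
            except ValueError as exc:
                raise FormatError(f"unparseable matrix body: {exc}") from exc
    if probs.ndim != 2 or probs.shape[0] != probs.shape[1]:
        raise FormatError(f"matrix is not square: shape {probs.shape}")
    if not np.isfinite(probs).all():
        bad = np.unravel_index(int(np.argmin(np.isfinite(probs))), probs.shape)
        raise FormatError(f"non-finite entry at (i, j) = {bad}")
    if (probs < 0).any() or (probs > 1).any():
        bad = np.unravel_index(int(np.argmax((probs < 0) | (probs > 1))),
                               probs.shape)
        raise FormatError(f"entry out of [0, 1] at (i, j) = {bad}")
    probs = _symmetrize_checked(probs)
    return ContactMap(probs, seg)


# ---------------------------------------------------------------------------
# gene-density tracks
# ---------------------------------------------------------------------------

def write_gene_track(track: GeneDensityTrack, segment: SegmentSpec, path) -> None:
    """4-column BED-like TSV: chrom, start, end, count."""
    with open(path, "w") as fh:
        for i, v in enumerate(track.density):
            start = segment.bin_start_bp(i)
            fh.write(f"{segment.chrom_label}\t{start}\t"
                     f"{start + segment.resolution_bp}\t{format(v, '.17g')}\n")


def read_gene_track(path) -> GeneDensityTrack:
    values = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"line {line_no}: expected 4 columns")
            values.append(float(parts[3]))
    return GeneDensityTrack(np.array(values))


# ---------------------------------------------------------------------------
# trajectories and landscapes
# ---------------------------------------------------------------------------

def save_trajectory(traj: Trajectory, path) -> None:
    np.savez_compressed(Path(path), frames=traj.frames, times=traj.times,
                        provenance=json.dumps(traj.provenance))


def load_trajectory(path) -> Trajectory:
    with np.load(Path(path)) as z:
        return Trajectory(z["frames"], z["times"],
                          json.loads(str(z["provenance"])))


def save_landscape(landscape: Landscape, path) -> None:
    extra = {}
    if landscape.fit_report is not None:
        extra["fit_report"] = json.dumps(dataclasses.asdict(landscape.fit_report))
    if landscape.final_conformation is not None:
        extra["final_positions"] = landscape.final_conformation.positions
    if landscape.final_pool:
        extra["final_pool"] = np.stack(
            [c.positions for c in landscape.final_pool])
    if landscape.segment is not None:
        extra["segment"] = json.dumps(dataclasses.asdict(landscape.segment))
    np.savez_compressed(
        Path(path), alpha=landscape.alpha, target_id=np.array(landscape.target_id),
        params=json.dumps(dataclasses.asdict(landscape.params)), **extra)


def load_landscape(path) -> Landscape:
    with np.load(Path(path)) as z:
        params = PolymerParams(**json.loads(str(z["params"])))
        report = None
        if "fit_report" in z:
            report = FitReport(**json.loads(str(z["fit_report"])))
        final = None
        if "final_positions" in z:
            final = Conformation(z["final_positions"])
        segment = None
        if "segment" in z:
            segment = SegmentSpec(**json.loads(str(z["segment"])))
        pool = None
        if "final_pool" in z:
            pool = [Conformation(p) for p in z["final_pool"]]
        return Landscape(z["alpha"], params, str(z["target_id"]), report,
                         final, segment, pool)


def export_pdb(frames, path, chain_id: str = "A") -> None:
    """Multi-model PDB-like text with one pseudo-atom (CA) per bead.

    Coordinates are written in sigma units scaled by 10 so typical viewers
    render sensible bond lengths.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    with open(path, "w") as fh:
        for m, frame in enumerate(frames, 1):
            fh.write(f"MODEL     {m:4d}\n")
            for i, (x, y, z) in enumerate(frame, 1):
                fh.write(
                    f"ATOM  {i % 100000:5d}  CA  BED {chain_id}{i % 10000:4d}"
                    f"    {10 * x:8.3f}{10 * y:8.3f}{10 * z:8.3f}"
                    f"  1.00  0.00           C\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
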