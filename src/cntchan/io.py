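"""File formats: XYZ / multi-model PDB structures and trajectories,
umbrella-window series with the de-facto WHAM metadata layout, delimited
result tables and YAML run configuration.

Conventions: lengths in Å, times in ns, 0-based frame indexing.  XYZ
comment lines carry ``t=<ns> box=<lx,ly,lz>`` and an optional fifth column
holds the group tag.  PDB files follow the fixed-width standard with
CHARMM-style residue names encoding the group tags (POT/SOD/CLA ions,
TIP3 water); partial charges go to the B-factor column when requested.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .atoms import ELEMENT_TAGS, AtomSet, Trajectory
from .wham import UmbrellaWindow

__all__ = [
    "write_xyz", "read_xyz", "write_pdb", "read_pdb", "read_trajectory",
    "write_charge_table", "write_wham_windows", "read_wham_metadata",
    "write_table", "events_to_table", "flux_to_table", "load_config",
]

TAG_TO_RES = {
    "wall_C": "CNT", "carbonyl_C": "CBC", "carbonyl_O": "CBO",
    "graphene_C": "GRA", "water_O": "TIP3", "water_H": "TIP3",
    "ion_K": "POT", "ion_Na": "SOD", "ion_Cl": "CLA",
}
RES_TO_TAG = {
    "CNT": "wall_C", "CBC": "carbonyl_C", "CBO": "carbonyl_O",
    "GRA": "graphene_C", "POT": "ion_K", "SOD": "ion_Na", "CLA": "ion_Cl",
}


def _frames_of(obj):
    if isinstance(obj, AtomSet):
        yield 0.0, obj.positions, obj.elements, obj.tags, None
    else:
        for f in range(obj.n_frames):
            yield obj.times[f], obj.positions[f], obj.elements, obj.tags, obj.box


def write_xyz(obj: AtomSet | Trajectory, path) -> None:
    """Write a structure or multi-frame trajectory as (extended) XYZ."""
    with open(path, "w") as fh:
        for t, pos, elements, tags, box in _frames_of(obj):
            fh.write(f"{len(pos)}\n")
            comment = f"t={t:.6f}"
            if box is not None:
                comment += " box=" + ",".join(f"{b:.4f}" for b in box)
            fh.write(comment + "\n")
            for el, p, tag in zip(elements, pos, tags):
                fh.write(f"{el:<2s} {p[0]:14.6f} {p[1]:14.6f} {p[2]:14.6f} "
                         f"{tag}\n")


def read_xyz(path, frame_dt: float = 0.01) -> Trajectory:
    """Read a (multi-frame) XYZ file written by :func:`write_xyz`.

    Files without the comment-line time key get ``frame index * frame_dt``;
    files without the tag column get tags inferred from the element.
    """
    frames, times, box = [], [], None
    tags = elements = None
    with open(path) as fh:
        lines = fh.read().split("\n")
    i, fidx = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        comment = lines[i + 1]
        t = fidx * frame_dt
        for token in comment.split():
            if token.startswith("t="):
                t = float(token[2:])
            elif token.startswith("box="):
                box = np.array([float(v) for v in token[4:].split(",")])
        pos = np.empty((n, 3))
        f_el, f_tag = [], []
        for k in range(n):
            parts = lines[i + 2 + k].split()
            el = parts[0]
            pos[k] = [float(v) for v in parts[1:4]]
            tag = parts[4] if len(parts) > 4 else None
            if tag is None:
                if el not in ELEMENT_TAGS:
                    raise ValueError(f"unknown element {el!r} without a tag")
                tag = ELEMENT_TAGS[el]
            f_el.append(el)
            f_tag.append(tag)
        if tags is None:
            tags, elements = f_tag, f_el
        elif len(f_tag) != len(tags):
            raise ValueError("inconsistent atom counts across frames")
        frames.append(pos)
        times.append(t)
        i += 2 + n
        fidx += 1
    return Trajectory(np.stack(frames), np.array(tags, object),
                      np.array(elements, object), np.array(times), box,
                      meta={"source": str(path)})


def write_pdb(obj: AtomSet | Trajectory, path,
              charges_in_bfactor: bool = True) -> None:
    """Write a structure or trajectory as (multi-model) fixed-width PDB."""
    charges = obj.charges if isinstance(obj, AtomSet) else None
    with open(path, "w") as fh:
        multi = not isinstance(obj, AtomSet)
        for fi, (t, pos, elements, tags, box) in enumerate(_frames_of(obj)):
            if multi:
                fh.write(f"MODEL     {fi + 1:4d}\n")
            for k, (el, p, tag) in enumerate(zip(elements, pos, tags)):
                res = TAG_TO_RES[tag]
                b = charges[k] if (charges_in_bfactor and charges is not None) else 0.0
                name = el[:4]
                fh.write(
                    f"ATOM  {(k + 1) % 100000:5d} {name:<4s} {res:<4s}"
                    f"A{(k % 9999) + 1:4d}    "
                    f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}{1.0:6.2f}{b:6.2f}"
                    f"          {el:>2s}\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def read_pdb(path, frame_dt: float = 0.01) -> Trajectory:
    """Read a (multi-model) PDB written by :func:`write_pdb`."""
    frames, cur = [], []
    tags = elements = None
    f_el, f_tag = [], []
    charges = []
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec in ("ATOM  ", "HETATM"):
                cur.append([float(line[30:38]), float(line[38:46]),
                            float(line[46:54])])
                if tags is None:
                    el = line[76:78].strip() or line[12:16].strip()[0]
                    res = line[17:21].strip()
                    if res == "TIP3":
                        tag = "water_O" if el == "O" else "water_H"
                    elif res in RES_TO_TAG:
                        tag = RES_TO_TAG[res]
                    elif el in ELEMENT_TAGS:
                        tag = ELEMENT_TAGS[el]
                    else:
                        raise ValueError(f"unknown element {el!r}")
                    f_el.append(el)
                    f_tag.append(tag)
                    charges.append(float(line[60:66] or 0.0))
            elif rec.strip() in ("ENDMDL", "END"):
                if cur:
                    if tags is None:
                        tags, elements = f_tag, f_el
                    elif len(cur) != len(tags):
                        raise ValueError("inconsistent atom counts across models")
                    frames.append(np.array(cur))
                    cur = []
    if cur:
        if tags is None:
            tags, elements = f_tag, f_el
        frames.append(np.array(cur))
    times = frame_dt * np.arange(len(frames))
    traj = Trajectory(np.stack(frames), np.array(tags, object),
                      np.array(elements, object), times,
                      meta={"source": str(path)})
    traj.meta["charges"] = np.array(charges)
    return traj


def read_trajectory(path, fmt: str | None = None,
                    frame_dt: float = 0.01) -> Trajectory:
    """Read a trajectory, format inferred from the extension by default."""
    if fmt is None:
        fmt = Path(path).suffix.lstrip(".").lower()
    if fmt == "xyz":
        return read_xyz(path, frame_dt)
    if fmt == "pdb":
        return read_pdb(path, frame_dt)
    raise ValueError(f"unsupported trajectory format {fmt!r}")


def write_charge_table(atoms: AtomSet, path) -> None:
    """Delimited sidecar: group tag and charge per distinct tag."""
    rows = []
    for tag in dict.fromkeys(atoms.tags):
        q = atoms.charges[atoms.tags == tag]
        rows.append({"tag": tag, "charge": float(q[0]), "count": int(len(q))})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_wham_windows(windows: list[UmbrellaWindow], outdir,
                       dt: float = 0.001, metadata_name: str = "metadata.txt"
                       ) -> Path:
    """Write per-window (time, z) series plus the standard metadata file.

    The metadata file lists ``path center spring_k`` per window, the layout
    consumed by standard WHAM implementations.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta_path = outdir / metadata_name
    with open(meta_path, "w") as meta:
        for i, w in enumerate(windows):
            fname = f"window_{i:03d}.dat"
            ts = dt * np.arange(len(w.samples))
            np.savetxt(outdir / fname, np.column_stack([ts, w.samples]),
                       fmt="%.6f")
            meta.write(f"{fname} {w.center:.4f} {w.spring_k:.4f}\n")
    return meta_path


def read_wham_metadata(path) -> list[UmbrellaWindow]:
    """Read a WHAM metadata file and its per-window time series."""
    path = Path(path)
    windows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            series = path.parent / parts[0] if not os.path.isabs(parts[0]) \
                else Path(parts[0])
            data = np.loadtxt(series)
            samples = data[:, 1] if data.ndim > 1 else data
            windows.append(UmbrellaWindow(center=float(parts[1]),
                                          spring_k=float(parts[2]),
                                          samples=samples))
    if not windows:
        raise ValueError(f"no windows listed in {path}")
    return windows


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def events_to_table(events) -> pd.DataFrame:
    return pd.DataFrame([{
        "species": e.species, "atom_index": e.atom_index,
        "entry_frame": e.entry_frame, "exit_frame": e.exit_frame,
        "mode": e.mode, "site_path": "-".join(e.site_path),
        "radial_mean": e.radial_mean,
    } for e in events])


def flux_to_table(series) -> pd.DataFrame:
    data = {"time_ns": series.time}
    for sp, c in series.counts.items():
        data[sp] = c
    return pd.DataFrame(data)


def load_config(path) -> dict:
    """Load a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a mapping")
    return cfg
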