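"""Extended-XYZ trajectory IO and CSV table output.

One record per frame: a count line, then a comment line carrying
``time_ps=<t> box=<Lx> <Ly> <Lz> [temperature_K=<T>]``, then one line per
molecule with a species tag (``W`` water, ``L`` lactose) and x, y, z in Å.
Coordinates are written with 17 significant digits so a write/read round
trip is bit-faithful.  Only cubic boxes are supported; the three box
entries must agree.
"""
from __future__ import annotations

import io
import os

import numpy as np
import pandas as pd

from .datamodel import SPECIES_TAG, TAG_SPECIES, Frame, Trajectory
from .errors import DomainError, TrajectoryFormatError


def write_trajectory(traj: Trajectory, path: os.PathLike | str) -> None:
    """Write a trajectory as extended XYZ (full float precision)."""
    if not isinstance(traj, Trajectory):
        raise DomainError("write_trajectory expects a Trajectory")
    with open(path, "w") as fh:
        for frame in traj:
            if frame.n_molecules < 1:
                raise DomainError("cannot write a frame with no molecules")
            fh.write(f"{frame.n_molecules}\n")
            t, b = repr(float(frame.time)), repr(float(frame.box_side))
            comment = f"time_ps={t} box={b} {b} {b}"
            if traj.temperature is not None:
                comment += f" temperature_K={float(traj.temperature)!r}"
            fh.write(comment + "\n")
            for tag, (x, y, z) in zip(
                    (SPECIES_TAG[s] for s in frame.species), frame.positions):
                fh.write(f"{tag} {float(x)!r} {float(y)!r} {float(z)!r}\n")


def _parse_comment(comment: str, frame_idx: int, line_no: int):
    fields = dict(tok.split("=", 1) for tok in comment.replace(
        "box=", "box=@").split() if "=" in tok)
    # box spans three whitespace-separated values; re-extract it verbatim
    time = None
    if "time_ps" in fields:
        time = float(fields["time_ps"])
    if "box" not in comment:
        raise TrajectoryFormatError("missing box metadata in comment line",
                                    frame=frame_idx, line=line_no)
    after = comment.split("box=", 1)[1].split()
    if len(after) < 3:
        raise TrajectoryFormatError("box metadata needs three lengths",
                                    frame=frame_idx, line=line_no)
    try:
        bx, by, bz = (float(v) for v in after[:3])
    except ValueError as exc:
        raise TrajectoryFormatError(f"unparseable box metadata: {exc}",
                                    frame=frame_idx, line=line_no)
    if not (bx == by == bz):
        raise TrajectoryFormatError("only cubic boxes are supported",
                                    frame=frame_idx, line=line_no)
    temp = float(fields["temperature_K"]) if "temperature_K" in fields else None
    return time, bx, temp


def read_trajectory(path: os.PathLike | str,
                    box_side: float | None = None) -> Trajectory:
    """Read an extended-XYZ trajectory.

    ``box_side`` supplies the box for plain-XYZ files whose comment lines
    carry no ``box=`` metadata; frame times then default to the frame
    index.  Frames must agree in molecule count, species labels and box.
    """
    frames: list[Frame] = []
    temperature = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frame_idx = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            count = int(lines[i].strip())
        except ValueError:
            raise TrajectoryFormatError(
                f"expected a molecule count, got {lines[i]!r}",
                frame=frame_idx, line=i + 1)
        if count < 1:
            raise TrajectoryFormatError("frame must contain >= 1 molecule",
                                        frame=frame_idx, line=i + 1)
        if i + 1 + count >= len(lines) + 1 and i + 1 >= len(lines):
            raise TrajectoryFormatError("truncated frame header",
                                        frame=frame_idx, line=i + 1)
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        if "box=" in comment:
            time, box, temp = _parse_comment(comment, frame_idx, i + 2)
        elif box_side is not None:
            time, box, temp = None, box_side, None
        else:
            raise TrajectoryFormatError(
                "missing box metadata and no sidecar box_side given",
                frame=frame_idx, line=i + 2)
        if temp is not None:
            temperature = temp
        if time is None:
            time = float(frame_idx)
        body = lines[i + 2:i + 2 + count]
        if len(body) < count:
            raise TrajectoryFormatError(
                f"frame declares {count} molecules but file ends after "
                f"{len(body)}", frame=frame_idx, line=i + 2 + len(body))
        species = []
        coords = np.empty((count, 3))
        for j, ln in enumerate(body):
            parts = ln.split()
            if len(parts) != 4:
                raise TrajectoryFormatError(
                    f"expected 'TAG x y z', got {ln!r}",
                    frame=frame_idx, line=i + 3 + j)
            tag = parts[0]
            if tag not in TAG_SPECIES:
                raise TrajectoryFormatError(
                    f"unknown species tag {tag!r} (expected W or L)",
                    frame=frame_idx, line=i + 3 + j)
            species.append(TAG_SPECIES[tag])
            try:
                coords[j] = [float(v) for v in parts[1:]]
            except ValueError as exc:
                raise TrajectoryFormatError(f"unparseable coordinate: {exc}",
                                            frame=frame_idx, line=i + 3 + j)
        frames.append(Frame(time=time, positions=coords,
                            species=np.array(species, dtype=object),
                            box_side=box))
        i += 2 + count
        frame_idx += 1
    if not frames:
        raise TrajectoryFormatError("file contains no frames", frame=0)
    ref = frames[0]
    for k, f in enumerate(frames):
        if f.n_molecules != ref.n_molecules:
            raise TrajectoryFormatError(
                f"molecule count changed from {ref.n_molecules} to "
                f"{f.n_molecules}", frame=k)
    dt = frames[1].time - frames[0].time if len(frames) > 1 else None
    return Trajectory(frames=frames, dt_record=dt, temperature=temperature)


def write_table(df: pd.DataFrame, path: os.PathLike | str,
                config_hash: str | None = None) -> None:
    """Write an analysis table as CSV, optionally stamped with a config hash.

    The hash is carried in a ``#``-prefixed comment line so the file stays
    plain CSV for readers that skip comments.
    """
    buf = io.StringIO()
    if config_hash is not None:
        buf.write(f"# config_hash={config_hash}\n")
    df.to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_table(path: os.PathLike | str) -> tuple[pd.DataFrame, str | None]:
    """Read a CSV written by :func:`write_table`; returns (df, config_hash)."""
    config_hash = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# config_hash="):
        config_hash = first.strip().split("=", 1)[1]
    df = pd.read_csv(path, comment="#")
    return df, config_hash
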