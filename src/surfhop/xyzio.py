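"""XYZ geometry/trajectory reading and writing.

Standard dialect: atom-count line, comment line, then ``element x y z`` in
Angstrom.  A comment line containing ``t= <value> fs`` is parsed into the
frame time (the dialect used by the per-frame trajectory dumps here).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

__all__ = ["Frame", "read_xyz", "write_xyz"]

_TIME_RE = re.compile(r"t\s*=\s*([-+0-9.eEdD]+)\s*fs")


@dataclass
class Frame:
    elements: list[str]
    positions: np.ndarray
    comment: str = ""
    time_fs: float | None = None


def read_xyz(path) -> list[Frame]:
    """Read all frames from an XYZ file."""
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        try:
            n = int(lines[k].split()[0])
        except (ValueError, IndexError):
            raise ValueError(f"{path}:{k + 1}: expected atom count, got {lines[k]!r}")
        if k + 2 + n > len(lines):
            raise ValueError(f"{path}:{k + 1}: truncated frame ({n} atoms declared)")
        comment = lines[k + 1].rstrip("\n")
        m = _TIME_RE.search(comment)
        time_fs = float(m.group(1).replace("D", "e").replace("d", "e")) if m else None
        elements = []
        pos = np.empty((n, 3))
        for j in range(n):
            parts = lines[k + 2 + j].split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{k + 3 + j}: malformed atom line {lines[k + 2 + j]!r}")
            elements.append(parts[0])
            pos[j] = [float(p) for p in parts[1:4]]
        frames.append(Frame(elements=elements, positions=pos, comment=comment, time_fs=time_fs))
        k += 2 + n
    return frames


def write_xyz(frames, path) -> None:
    """Write one frame or a list of frames to an XYZ file."""
    if isinstance(frames, Frame):
        frames = [frames]
    with open(path, "w") as fh:
        for fr in frames:
            comment = fr.comment
            if fr.time_fs is not None and "t=" not in comment:
                comment = (comment + f" t= {fr.time_fs:.4f} fs").strip()
            fh.write(f"{len(fr.elements)}\n{comment}\n")
            for el, (x, y, z) in zip(fr.elements, fr.positions):
                fh.write(f"{el:2s} {x:18.10f} {y:18.10f} {z:18.10f}\n")
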