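"""Molecular frames, an extended-XYZ dialect, and toy host-guest fixtures.

A :class:`Frame` holds element labels and coordinates (nm) plus the host
axis definition (origin and unit direction) carried on the XYZ comment line.
The toy generator builds coarse host + ligand + water-bead geometries for the
bound (B, ligand in a dry cavity) and unbound (U, ligand solvated outside the
funnel mouth, water filling the cavity) states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

#: Element labels treated as water oxygens by the descriptor module.
WATER_LABELS = frozenset({"OW", "W"})

# Toy host geometry (nm): cavity is a cylinder along -z, entrance at z=0.
CAVITY_DEPTH = 0.8
CAVITY_RADIUS = 0.3
#: Desolvation margin (nm) around the cavity in bound-state frames: waters are
#: excluded out to one switching-function width beyond the cavity walls, so
#: deep cavity points read near-zero coordination (the rational switching
#: function has a long r^-6 tail, so "zero" means small against the ~3 bulk
#: value, not exactly 0).
DRY_MARGIN = 0.3
TOY_BOX = np.array([2.4, 2.4, 2.4])  # x,y in [-1.2,1.2], z in [-0.8,1.6]


@dataclass
class Frame:
    """One configuration: labelled beads plus the host axis definition."""

    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3), nm
    axis_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.shape != (len(self.elements), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.elements)} elements"
            )
        self.axis_origin = np.asarray(self.axis_origin, dtype=float)
        d = np.asarray(self.axis_direction, dtype=float)
        norm = np.linalg.norm(d)
        if norm == 0:
            raise ValueError("axis_direction must be nonzero")
        self.axis_direction = d / norm

    def select(self, labels: Iterable[str] | None = None) -> np.ndarray:
        """Coordinates of beads whose element label is in ``labels`` (all if None)."""
        if labels is None:
            return self.coords
        labels = set(labels)
        mask = [e in labels for e in self.elements]
        return self.coords[np.asarray(mask, dtype=bool)]

    @property
    def water_oxygens(self) -> np.ndarray:
        return self.select(WATER_LABELS)


def _fmt_vec(v: np.ndarray) -> str:
    return ",".join(f"{x:.10g}" for x in v)


def write_xyz_frames(frames: Sequence[Frame], path: str | Path) -> None:
    """Write frames as extended-XYZ: count line, comment line with axis/box."""
    lines: list[str] = []
    for fr in frames:
        lines.append(str(len(fr.elements)))
        comment = (
            f"axis_origin={_fmt_vec(fr.axis_origin)} "
            f"axis_direction={_fmt_vec(fr.axis_direction)}"
        )
        if fr.box is not None:
            comment += f" box={_fmt_vec(fr.box)}"
        lines.append(comment)
        for el, xyz in zip(fr.elements, fr.coords):
            lines.append(f"{el} {xyz[0]:.10g} {xyz[1]:.10g} {xyz[2]:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz_frames(path: str | Path) -> list[Frame]:
    """Read an extended-XYZ file; frames may have differing atom counts.

    An empty file yields an empty list. A count line that does not match the
    number of atom lines raises ``ValueError`` with the line number.
    """
    text = Path(path).read_text().splitlines()
    frames: list[Frame] = []
    i = 0
    while i < len(text):
        if not text[i].strip():
            i += 1
            continue
        try:
            n = int(text[i].strip())
        except ValueError:
            raise ValueError(f"{path}: line {i + 1}: expected atom count") from None
        if i + 1 + n >= len(text) + 1 and n > 0 and i + 1 + n > len(text):
            raise ValueError(f"{path}: line {i + 1}: frame truncated ({n} atoms declared)")
        comment = text[i + 1] if i + 1 < len(text) else ""
        meta: dict[str, np.ndarray] = {}
        for token in comment.split():
            if "=" in token:
                key, _, val = token.partition("=")
                try:
                    meta[key] = np.array([float(x) for x in val.split(",")])
                except ValueError:
                    pass
        elements, coords = [], []
        for j in range(n):
            lineno = i + 2 + j
            parts = text[lineno].split()
            if len(parts) < 4:
                raise ValueError(f"{path}: line {lineno + 1}: malformed atom line")
            elements.append(parts[0])
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
        frames.append(
            Frame(
                elements=elements,
                coords=np.asarray(coords).reshape(n, 3),
                axis_origin=meta.get("axis_origin", np.zeros(3)),
                axis_direction=meta.get("axis_direction", np.array([0.0, 0.0, 1.0])),
                box=meta.get("box"),
            )
        )
        i += 2 + n
    return frames


def _in_cavity(points: np.ndarray) -> np.ndarray:
    """Boolean mask for points inside the toy host cavity."""
    r = np.hypot(points[:, 0], points[:, 1])
    return (points[:, 2] < 0.0) & (points[:, 2] > -CAVITY_DEPTH) & (r < CAVITY_RADIUS)


def _in_dry_zone(points: np.ndarray) -> np.ndarray:
    """Cavity plus the desolvation margin (bound-state water exclusion)."""
    r = np.hypot(points[:, 0], points[:, 1])
    return (points[:, 2] < DRY_MARGIN) & (r < CAVITY_RADIUS + DRY_MARGIN)


def toy_host_guest_frames(
    n_frames: int,
    n_waters: int,
    state_label: str,
    seed: int,
    n_host_beads: int = 12,
    jitter: float = 0.03,
) -> list[Frame]:
    """Generate toy B/U frames for the descriptor module.

    In the bound state the two-bead ligand sits deep in the cavity and water
    beads are excluded from it and a desolvation margin around it; in the
    unbound state the ligand floats beyond the funnel mouth and water fills
    the whole box, cavity included.

    Labels: ``HB`` host, ``LG`` ligand, ``OW`` water oxygen beads.
    """
    if state_label not in ("B", "U"):
        raise ValueError(f"state_label must be 'B' or 'U', got {state_label!r}")
    rng = np.random.default_rng(seed)
    lo = np.array([-TOY_BOX[0] / 2, -TOY_BOX[1] / 2, -CAVITY_DEPTH])
    hi = np.array([TOY_BOX[0] / 2, TOY_BOX[1] / 2, TOY_BOX[2] - CAVITY_DEPTH])
    # static host scaffold: a ring of beads around the cavity entrance
    angles = np.linspace(0, 2 * np.pi, n_host_beads, endpoint=False)
    host = np.column_stack(
        [
            (CAVITY_RADIUS + 0.1) * np.cos(angles),
            (CAVITY_RADIUS + 0.1) * np.sin(angles),
            np.full(n_host_beads, -0.05),
        ]
    )
    frames = []
    for _ in range(n_frames):
        if state_label == "B":
            ligand = np.array([[0.0, 0.0, -0.55], [0.0, 0.0, -0.30]])
        else:
            ligand = np.array([[0.0, 0.0, 1.15], [0.0, 0.0, 1.40]])
        ligand = ligand + rng.normal(scale=jitter, size=ligand.shape)
        waters = np.empty((0, 3))
        if n_waters > 0:
            # rejection-sample uniform waters; exclude the cavity in B
            need = n_waters
            chunks = []
            while need > 0:
                cand = rng.uniform(lo, hi, size=(max(2 * need, 16), 3))
                if state_label == "B":
                    cand = cand[~_in_dry_zone(cand)]
                chunks.append(cand[:need])
                need -= len(chunks[-1])
            waters = np.vstack(chunks)
        elements = (
            ["HB"] * n_host_beads + ["LG"] * len(ligand) + ["OW"] * len(waters)
        )
        coords = np.vstack([host, ligand, waters])
        frames.append(Frame(elements=elements, coords=coords, box=TOY_BOX.copy()))
    return frames
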