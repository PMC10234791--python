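"""Reading and writing 2D facial-landmark files.

Two plain-text dialects are supported:

* **TEM** (Webmorph / Psychomorph): first line is the landmark count,
  followed by one ``x y`` pair per line.  Webmorph exports append a
  line-connectivity block after the coordinates; it is skipped on read
  and never written.
* **TPS** (tpsDig lineage): ``LM=<count>`` header, coordinate lines,
  optional ``ID=`` / ``IMAGE=`` keys.

Coordinates are stored exactly as read, in image convention (y grows
downward).  Shape analysis is invariant to that choice, so no axis flip
is performed at I/O time.  Point order is semantic — landmark *k* on one
face corresponds to landmark *k* on every other face — and is never
permuted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "LandmarkConfiguration",
    "LandmarkParseError",
    "read_tem",
    "write_tem",
    "read_tps",
    "write_tps",
    "validate_directory",
]


class LandmarkParseError(ValueError):
    """Raised when a landmark file is malformed."""


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One face as an ordered set of 2D landmark points.

    Parameters
    ----------
    face_id : str
        Opaque identifier (typically the file stem).
    points : ndarray of shape (n_points, 2)
        Landmark coordinates in image pixels.
    """

    face_id: str
    points: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must be (n, 2), got {pts.shape}")
        if pts.shape[0] < 3:
            raise ValueError(f"need >= 3 landmarks, got {pts.shape[0]}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("landmark coordinates must be finite")
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def centroid_size(self) -> float:
        """Square root of summed squared distances from the centroid."""
        centered = self.points - self.centroid()
        return float(np.sqrt((centered**2).sum()))


def _parse_xy(line: str, path_hint: str) -> tuple[float, float]:
    parts = line.split()
    if len(parts) < 2:
        raise LandmarkParseError(f"{path_hint}: expected 'x y', got {line!r}")
    try:
        return float(parts[0]), float(parts[1])
    except ValueError as exc:
        raise LandmarkParseError(
            f"{path_hint}: non-numeric coordinate in {line!r}"
        ) from exc


def read_tem(source, face_id: str | None = None) -> LandmarkConfiguration:
    """Read a Webmorph TEM file.

    Parameters
    ----------
    source : str, Path, or open text file
        Path to the file, or the file content itself as a string
        containing newlines, or a file-like object.
    face_id : str, optional
        Identifier for the face; defaults to the file stem when a path
        is given, else ``""``.
    """
    text, hint, inferred = _slurp(source)
    if face_id is None:
        face_id = inferred
    lines = [ln.strip() for ln in text.splitlines()]
    lines = [ln for ln in lines if ln]
    if not lines:
        raise LandmarkParseError(f"{hint}: empty file")
    try:
        declared = int(lines[0])
    except ValueError as exc:
        raise LandmarkParseError(
            f"{hint}: first line must be the point count, got {lines[0]!r}"
        ) from exc
    coord_lines = lines[1 : 1 + declared]
    if len(coord_lines) < declared:
        raise LandmarkParseError(
            f"{hint}: declared {declared} points but found only "
            f"{len(coord_lines)} coordinate lines"
        )
    # Anything after the declared coordinates is the Webmorph line-
    # connectivity block; verify we are not silently swallowing extra
    # coordinate rows before it.
    if len(lines) > 1 + declared:
        nxt = lines[1 + declared].split()
        if len(nxt) >= 2 and _looks_like_pair(nxt):
            raise LandmarkParseError(
                f"{hint}: more coordinate lines than the declared {declared}"
            )
    pts = np.array([_parse_xy(ln, hint) for ln in coord_lines], dtype=float)
    return LandmarkConfiguration(face_id=face_id, points=pts)


def _looks_like_pair(parts: list[str]) -> bool:
    try:
        float(parts[0]), float(parts[1])
    except ValueError:
        return False
    # Webmorph connectivity rows are small integers (line lengths /
    # point indices); a row of two non-integer floats is a coordinate.
    return not all(float(p) == int(float(p)) for p in parts[:2])


def write_tem(config: LandmarkConfiguration, dest=None) -> str:
    """Serialise a configuration to the TEM dialect.

    Returns the text; additionally writes it to ``dest`` (path or
    file-like) when given.  ``read_tem(write_tem(c))`` reproduces ``c``
    exactly on point count and to better than 1e-9 on coordinates.
    """
    lines = [str(config.n_points)]
    lines += [f"{x:.17g} {y:.17g}" for x, y in config.points]
    text = "\n".join(lines) + "\n"
    _spill(text, dest)
    return text


def read_tps(source, face_id: str | None = None) -> LandmarkConfiguration:
    """Read a single-specimen TPS file (``LM=``, coordinates, ``ID=``)."""
    text, hint, inferred = _slurp(source)
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].upper().startswith("LM="):
        raise LandmarkParseError(f"{hint}: missing LM= header")
    try:
        declared = int(lines[0].split("=", 1)[1])
    except ValueError as exc:
        raise LandmarkParseError(f"{hint}: bad LM= count {lines[0]!r}") from exc
    coords: list[tuple[float, float]] = []
    file_id = None
    for ln in lines[1:]:
        upper = ln.upper()
        if upper.startswith(("ID=", "IMAGE=", "SCALE=")):
            if upper.startswith("ID="):
                file_id = ln.split("=", 1)[1].strip()
            continue
        coords.append(_parse_xy(ln, hint))
    if len(coords) != declared:
        raise LandmarkParseError(
            f"{hint}: LM={declared} but {len(coords)} coordinate lines"
        )
    if face_id is None:
        face_id = file_id if file_id else inferred
    return LandmarkConfiguration(face_id=face_id, points=np.array(coords))


def write_tps(config: LandmarkConfiguration, dest=None) -> str:
    """Serialise a configuration to TPS (``LM=``, coordinates, ``ID=``)."""
    lines = [f"LM={config.n_points}"]
    lines += [f"{x:.17g} {y:.17g}" for x, y in config.points]
    lines.append(f"ID={config.face_id}")
    text = "\n".join(lines) + "\n"
    _spill(text, dest)
    return text


def read_landmark_dir(
    directory, pattern: str = "*.tem"
) -> list[LandmarkConfiguration]:
    """Read every landmark file matching ``pattern`` under ``directory``."""
    directory = Path(directory)
    reader = read_tps if pattern.endswith(("tps", "TPS")) else read_tem
    configs = [reader(p) for p in sorted(directory.glob(pattern))]
    if not configs:
        raise FileNotFoundError(f"no {pattern} files under {directory}")
    return configs


def validate_directory(
    directory, pattern: str = "*.tem"
) -> list[tuple[str, str]]:
    """Check every landmark file in a directory; return (file, problem) pairs.

    Problems include parse failures and point counts that disagree with
    the majority of files (all faces in one study must share a template).
    """
    directory = Path(directory)
    problems: list[tuple[str, str]] = []
    counts: dict[str, int] = {}
    reader = read_tps if pattern.endswith(("tps", "TPS")) else read_tem
    for path in sorted(directory.glob(pattern)):
        try:
            cfg = reader(path)
        except (LandmarkParseError, ValueError) as exc:
            problems.append((path.name, str(exc)))
            continue
        counts[path.name] = cfg.n_points
    if counts:
        majority = max(set(counts.values()), key=list(counts.values()).count)
        for name, n in counts.items():
            if n != majority:
                problems.append(
                    (name, f"{n} landmarks, expected {majority} like the rest")
                )
    return problems


def _slurp(source) -> tuple[str, str, str]:
    """Return (text, hint-for-errors, inferred face_id)."""
    if hasattr(source, "read"):
        return source.read(), "<stream>", ""
    if isinstance(source, Path) or (
        isinstance(source, str) and source.strip() and "\n" not in source
    ):
        path = Path(source)
        return path.read_text(), path.name, path.stem
    return str(source), "<text>", ""


def _spill(text: str, dest) -> None:
    if dest is None:
        return
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text)
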