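"""Plain-text I/O: square-matrix TSV, per-node vectors, coordinates, node sets.

Dialect: tab-separated, UTF-8, '.' decimal, no header for matrices and
vectors; a header row for coordinate tables. Floats are written in shortest
round-trip form so that write(read(x)) is byte-identical for canonical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_vector",
    "write_vector",
    "read_coordinates",
    "write_coordinates",
    "read_node_set",
    "write_node_set",
]

_SYMMETRY_TOL = 1e-10


def _fmt(x: float) -> str:
    return repr(float(x))


def read_matrix(path: str | Path, expected_n: int | None = None) -> np.ndarray:
    """Read a square TSV matrix, validating shape, finiteness and symmetry."""
    path = Path(path)
    rows: list[list[float]] = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            rows.append([float(tok) for tok in line.split("\t")])
        except ValueError as err:
            raise ValueError(f"{path}:{ln}: unparseable entry ({err})") from None
    m = np.array(rows, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{path}: not square (shape {m.shape})")
    if expected_n is not None and m.shape[0] != expected_n:
        raise ValueError(f"{path}: expected {expected_n} rows, got {m.shape[0]}")
    if not np.all(np.isfinite(m)):
        bad = np.argwhere(~np.isfinite(m))[0]
        raise ValueError(f"{path}: non-finite entry at row {bad[0]+1}, col {bad[1]+1}")
    asym = np.abs(m - m.T)
    if asym.max() > _SYMMETRY_TOL:
        i, j = np.unravel_index(asym.argmax(), asym.shape)
        raise ValueError(
            f"{path}: asymmetric beyond tolerance at cell "
            f"({i+1}, {j+1}): |{m[i, j]!r} - {m[j, i]!r}|"
        )
    return m


def write_matrix(path: str | Path, m: np.ndarray) -> None:
    lines = ["\t".join(_fmt(x) for x in row) for row in np.asarray(m, dtype=float)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_vector(path: str | Path, expected_n: int | None = None) -> np.ndarray:
    """Read a one-value-per-line TSV vector (states, maps, labels)."""
    path = Path(path)
    vals: list[float] = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            vals.append(float(line.strip()))
        except ValueError as err:
            raise ValueError(f"{path}:{ln}: unparseable entry ({err})") from None
    v = np.array(vals, dtype=float)
    if expected_n is not None and len(v) != expected_n:
        raise ValueError(f"{path}: expected {expected_n} values, got {len(v)}")
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{path}: non-finite value present")
    return v


def write_vector(path: str | Path, v: np.ndarray) -> None:
    Path(path).write_text(
        "\n".join(_fmt(x) for x in np.asarray(v, dtype=float)) + "\n"
    )


def read_coordinates(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a (node, x, y, z, hemisphere) TSV with header row."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines or lines[0].split("\t")[:1] != ["node"]:
        raise ValueError(f"{path}: missing 'node\\tx\\ty\\tz\\themisphere' header")
    coords, hemi = [], []
    for ln, line in enumerate(lines[1:], start=2):
        toks = line.split("\t")
        if len(toks) != 5:
            raise ValueError(f"{path}:{ln}: expected 5 columns, got {len(toks)}")
        coords.append([float(toks[1]), float(toks[2]), float(toks[3])])
        hemi.append(toks[4])
    return np.array(coords, dtype=float), np.array(hemi)


def write_coordinates(
    path: str | Path, coords: np.ndarray, hemisphere: np.ndarray
) -> None:
    lines = ["node\tx\ty\tz\themisphere"]
    for i, (xyz, h) in enumerate(zip(np.asarray(coords, dtype=float), hemisphere)):
        lines.append(
            f"n{i:03d}\t{_fmt(xyz[0])}\t{_fmt(xyz[1])}\t{_fmt(xyz[2])}\t{h}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_node_set(path: str | Path) -> np.ndarray:
    """Read a node set: one integer node index per line."""
    vals = [
        int(line.strip())
        for line in Path(path).read_text().splitlines()
        if line.strip()
    ]
    return np.array(sorted(vals), dtype=int)


def write_node_set(path: str | Path, nodes) -> None:
    Path(path).write_text(
        "\n".join(str(int(i)) for i in sorted(nodes)) + "\n"
    )
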