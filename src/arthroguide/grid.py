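"""Spatially-unique 2D grid patterns.

The silicone template's defining property, abstracted: a 2D array of marks
over a small alphabet in which every k×k contiguous window occurs at most
once, so any imaged k×k patch identifies its own global position on the
template (and hence on the skin).  This module generates such patterns by
seeded randomized fill with backtracking, verifies the uniqueness property
exhaustively, and localizes exact or corrupted windows.

A pattern with W = (rows−k+1)(cols−k+1) windows over alphabet size A can
only exist when W ≤ A^(k²); the generator enforces this counting bound up
front.  Randomized fill is not a perfect-map construction (de Bruijn tori
achieve W = A^(k²) exactly) but is simple, verifiable, and ample at
template scale, where W is far below the bound.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "GridPattern",
    "GridLocation",
    "UniquenessReport",
    "GridError",
    "PatternGenerationError",
    "generate_pattern",
    "verify_uniqueness",
    "extract_window",
    "localize",
    "localize_noisy",
    "min_window_hamming",
    "pattern_to_raster",
    "raster_to_cells",
]

DEFAULT_CELL_PITCH_MM = 5.0


class GridError(ValueError):
    pass


class PatternGenerationError(GridError):
    """The randomized search failed within its backtracking budget."""


@dataclass(frozen=True)
class GridPattern:
    """A unique-window pattern plus its physical cell pitch."""

    cells: np.ndarray
    k: int
    alphabet: int
    pitch_mm: float = DEFAULT_CELL_PITCH_MM
    seed: int | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.cells, dtype=np.int64)
        if c.ndim != 2:
            raise GridError("cells must be a 2D array")
        if self.k < 2:
            raise GridError("window size k must be >= 2")
        if c.shape[0] < self.k or c.shape[1] < self.k:
            raise GridError("pattern must be at least k x k")
        if self.alphabet < 2:
            raise GridError("alphabet size must be >= 2")
        if c.min() < 0 or c.max() >= self.alphabet:
            raise GridError("cell symbols must lie in [0, alphabet)")
        if self.pitch_mm <= 0:
            raise GridError("cell pitch must be positive")
        object.__setattr__(self, "cells", c)

    @property
    def rows(self) -> int:
        return int(self.cells.shape[0])

    @property
    def cols(self) -> int:
        return int(self.cells.shape[1])

    @property
    def n_windows(self) -> int:
        return (self.rows - self.k + 1) * (self.cols - self.k + 1)

    def windows(self) -> np.ndarray:
        """All k×k windows, shape (rows−k+1, cols−k+1, k, k)."""
        return sliding_window_view(self.cells, (self.k, self.k))

    def to_json(self) -> str:
        return json.dumps(
            {
                "rows": self.rows,
                "cols": self.cols,
                "k": self.k,
                "alphabet": self.alphabet,
                "pitch_mm": self.pitch_mm,
                "seed": self.seed,
                "cells": self.cells.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GridPattern":
        d = json.loads(text)
        return cls(
            cells=np.array(d["cells"]),
            k=d["k"],
            alphabet=d["alphabet"],
            pitch_mm=d.get("pitch_mm", DEFAULT_CELL_PITCH_MM),
            seed=d.get("seed"),
        )

    def to_text(self) -> str:
        return "\n".join(" ".join(str(v) for v in row) for row in self.cells)


@dataclass(frozen=True)
class GridLocation:
    """A window's top-left cell index and its physical position."""

    row: int
    col: int
    x_mm: float
    y_mm: float
    score: int = 0  # Hamming distance of the match; 0 = exact

    @classmethod
    def at(cls, row: int, col: int, pitch_mm: float, score: int = 0) -> "GridLocation":
        return cls(row=row, col=col, x_mm=col * pitch_mm, y_mm=row * pitch_mm, score=score)


@dataclass(frozen=True)
class UniquenessReport:
    passed: bool
    n_windows: int
    duplicates: tuple[tuple[tuple[int, int], tuple[int, int]], ...]


def counting_bound_ok(rows: int, cols: int, k: int, alphabet: int) -> bool:
    n_windows = (rows - k + 1) * (cols - k + 1)
    # A^(k*k) can overflow float; compare in log space.
    return n_windows <= 0 or np.log(n_windows) <= k * k * np.log(alphabet)


def generate_pattern(
    rows: int,
    cols: int,
    k: int,
    alphabet: int = 2,
    seed: int = 0,
    pitch_mm: float = DEFAULT_CELL_PITCH_MM,
    min_hamming: int = 1,
    max_nodes: int = 2_000_000,
    max_restarts: int = 50,
) -> GridPattern:
    """Generate a pattern whose k×k windows are all distinct.

    Seeded randomized row-major fill with chronological backtracking: a cell
    at (r, c) with r, c ≥ k−1 completes exactly one window, which must be
    new.  On exhausting ``max_nodes`` search steps the fill restarts with
    fresh symbol orderings; after ``max_restarts`` restarts the search fails
    explicitly — a non-unique pattern is never returned silently.
    Deterministic for a fixed seed.  Uniqueness is re-verified exhaustively
    before returning.

    ``min_hamming`` > 1 additionally requires every pair of windows to
    differ in at least that many cells, which makes noisy localization with
    up to ``(min_hamming − 1) // 2`` corrupted cells unambiguous.  This is a
    code-design constraint: feasible sizes shrink rapidly (a binary k=3
    pattern admits at most 40 windows at distance 3), so it usually needs a
    larger alphabet.
    """
    if k < 2 or rows < k or cols < k:
        raise GridError(f"need rows, cols >= k >= 2, got {rows}x{cols}, k={k}")
    if alphabet < 2:
        raise GridError("alphabet size must be >= 2")
    if not counting_bound_ok(rows, cols, k, alphabet):
        raise GridError(
            f"counting bound violated: {(rows - k + 1) * (cols - k + 1)} windows "
            f"exceed {alphabet}^{k * k} possible distinct windows"
        )
    if min_hamming < 1:
        raise GridError("min_hamming must be >= 1")
    rng = np.random.default_rng(seed)
    for _ in range(max_restarts):
        cells = _try_fill(rows, cols, k, alphabet, rng, max_nodes, min_hamming)
        if cells is not None:
            pattern = GridPattern(
                cells=cells, k=k, alphabet=alphabet, pitch_mm=pitch_mm, seed=seed
            )
            report = verify_uniqueness(pattern)
            if not report.passed:  # pragma: no cover - generator contract
                raise PatternGenerationError("internal error: duplicate windows")
            if min_hamming > 1 and min_window_hamming(pattern) < min_hamming:
                # pragma: no cover - generator contract
                raise PatternGenerationError("internal error: distance violated")
            return pattern
    raise PatternGenerationError(
        f"no unique-window pattern found for {rows}x{cols}, k={k}, "
        f"A={alphabet} within the backtracking budget"
    )


def _try_fill(
    rows: int,
    cols: int,
    k: int,
    alphabet: int,
    rng: np.random.Generator,
    max_nodes: int,
    min_hamming: int = 1,
) -> np.ndarray | None:
    cells = np.full((rows, cols), -1, dtype=np.int64)
    seen: set[tuple] = set()
    order = [(r, c) for r in range(rows) for c in range(cols)]
    # Per-cell shuffled symbol order, drawn once per fill attempt.
    sym_order = [rng.permutation(alphabet) for _ in order]
    next_try = [0] * len(order)
    placed_window: list[tuple | None] = [None] * len(order)
    i = 0
    nodes = 0
    while 0 <= i < len(order):
        nodes += 1
        if nodes > max_nodes:
            return None
        r, c = order[i]
        if placed_window[i] is not None:
            seen.discard(placed_window[i])
            placed_window[i] = None
        found = False
        while next_try[i] < alphabet:
            sym = int(sym_order[i][next_try[i]])
            next_try[i] += 1
            if r >= k - 1 and c >= k - 1:
                cells[r, c] = sym
                win = tuple(cells[r - k + 1 : r + 1, c - k + 1 : c + 1].ravel())
                if win in seen:
                    continue
                if min_hamming > 1 and seen:
                    arr = np.fromiter(
                        (x for w in seen for x in w), dtype=np.int64
                    ).reshape(len(seen), k * k)
                    if int((arr != np.array(win)).sum(axis=1).min()) < min_hamming:
                        continue
                seen.add(win)
                placed_window[i] = win
            else:
                cells[r, c] = sym
            found = True
            break
        if found:
            i += 1
        else:  # backtrack
            cells[r, c] = -1
            next_try[i] = 0
            i -= 1
    if i < 0:
        return None
    return cells


def verify_uniqueness(pattern: GridPattern, k: int | None = None) -> UniquenessReport:
    """Exhaustively check that no two k×k windows are identical."""
    k = pattern.k if k is None else k
    wins = sliding_window_view(pattern.cells, (k, k))
    nr, nc = wins.shape[:2]
    flat = wins.reshape(nr * nc, k * k)
    seen: dict[bytes, tuple[int, int]] = {}
    duplicates = []
    for idx in range(nr * nc):
        key = flat[idx].tobytes()
        loc = (idx // nc, idx % nc)
        if key in seen:
            duplicates.append((seen[key], loc))
        else:
            seen[key] = loc
    return UniquenessReport(
        passed=not duplicates, n_windows=nr * nc, duplicates=tuple(duplicates)
    )


def extract_window(pattern: GridPattern, row: int, col: int) -> np.ndarray:
    k = pattern.k
    if not (0 <= row <= pattern.rows - k and 0 <= col <= pattern.cols - k):
        raise GridError(f"window origin ({row}, {col}) out of bounds")
    return pattern.cells[row : row + k, col : col + k].copy()


def _check_window(window: np.ndarray, pattern: GridPattern) -> np.ndarray:
    w = np.asarray(window, dtype=np.int64)
    if w.shape != (pattern.k, pattern.k):
        raise GridError(f"window must be {pattern.k}x{pattern.k}, got {w.shape}")
    if w.min() < 0 or w.max() >= pattern.alphabet:
        raise GridError("window symbols outside the pattern's alphabet")
    return w


def _hamming_map(window: np.ndarray, pattern: GridPattern) -> np.ndarray:
    wins = pattern.windows()
    return (wins != window).sum(axis=(2, 3))


def localize(window: np.ndarray, pattern: GridPattern) -> GridLocation | None:
    """Exact-match localization; returns None when the window is absent.

    By the uniqueness invariant an exact match, if present, is unique.
    """
    w = _check_window(window, pattern)
    ham = _hamming_map(w, pattern)
    hits = np.argwhere(ham == 0)
    if len(hits) == 0:
        return None
    r, c = (int(v) for v in hits[0])
    return GridLocation.at(r, c, pattern.pitch_mm)


def localize_noisy(
    window: np.ndarray, pattern: GridPattern, max_mismatches: int = 0
) -> list[GridLocation]:
    """All locations within ``max_mismatches`` Hamming distance of the window,
    sorted by score then row-major order."""
    if max_mismatches < 0:
        raise GridError("max_mismatches must be >= 0")
    w = _check_window(window, pattern)
    ham = _hamming_map(w, pattern)
    hits = np.argwhere(ham <= max_mismatches)
    locs = [
        GridLocation.at(int(r), int(c), pattern.pitch_mm, score=int(ham[r, c]))
        for r, c in hits
    ]
    locs.sort(key=lambda g: (g.score, g.row, g.col))
    return locs


def min_window_hamming(pattern: GridPattern) -> int:
    """Minimum pairwise Hamming distance over all window pairs.

    Noisy localization with m mismatches is guaranteed unambiguous only
    when 2m < this distance.
    """
    k = pattern.k
    flat = pattern.windows().reshape(-1, k * k)
    n = flat.shape[0]
    if n < 2:
        raise GridError("need at least two windows")
    best = k * k + 1
    # Chunked pairwise comparison keeps memory bounded at large templates.
    chunk = max(1, 2_000_000 // (n * k * k))
    for start in range(0, n, chunk):
        block = flat[start : start + chunk]
        d = (block[:, None, :] != flat[None, :, :]).sum(axis=2)
        for i in range(d.shape[0]):
            d[i, start + i] = k * k + 1  # ignore self-comparison
        best = min(best, int(d.min()))
    return best


def pattern_to_raster(pattern: GridPattern, cell_px: int = 1) -> np.ndarray:
    """Block-constant raster image, one cell → cell_px × cell_px pixels."""
    if cell_px < 1:
        raise GridError("cell_px must be >= 1")
    return np.kron(pattern.cells, np.ones((cell_px, cell_px), dtype=np.int64))


def raster_to_cells(raster: np.ndarray, cell_px: int) -> np.ndarray:
    """Invert pattern_to_raster by per-block mode (majority vote)."""
    img = np.asarray(raster)
    if cell_px < 1 or img.shape[0] % cell_px or img.shape[1] % cell_px:
        raise GridError("raster dimensions must be multiples of cell_px")
    rows, cols = img.shape[0] // cell_px, img.shape[1] // cell_px
    blocks = img.reshape(rows, cell_px, cols, cell_px).swapaxes(1, 2).reshape(
        rows, cols, cell_px * cell_px
    )
    out = np.empty((rows, cols), dtype=np.int64)
    for r in range(rows):
        for c in range(cols):
            vals, counts = np.unique(blocks[r, c], return_counts=True)
            out[r, c] = vals[np.argmax(counts)]
    return out


def write_pgm(raster: np.ndarray, path, levels: int | None = None) -> None:
    """Plain-text PGM (P2) export for visual inspection / mold design."""
    img = np.asarray(raster, dtype=np.int64)
    maxval = int(img.max()) if levels is None else levels - 1
    maxval = max(maxval, 1)
    with open(path, "w") as fh:
        fh.write(f"P2\n{img.shape[1]} {img.shape[0]}\n{maxval}\n")
        for row in img:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")
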