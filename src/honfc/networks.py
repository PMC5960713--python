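"""Low-order and multi-level high-order functional connectivity networks.

A subject's resting-state signal is summarised as a ``T x R`` matrix of
ROI-averaged time courses (``T`` time points, ``R`` regions of interest).
The low-order network (LON, level 0) is the usual Pearson correlation
matrix between ROI time courses.  Each higher level is obtained by
correlating *FC profiles*: entry ``(i, j)`` of level ``k + 1`` is the
Pearson correlation between rows ``i`` and ``j`` of the level-``k``
matrix, after removing the entries at positions ``i`` and ``j`` from both
rows (a profile never includes the two regions being compared).  Iterating
this "correlation of correlations" step yields the hierarchy
``{LON, HON-1, ..., HON-t}``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger("honfc.networks")

__all__ = [
    "DegenerateInputError",
    "ROITimeSeries",
    "FCNetwork",
    "low_order_network",
    "high_order_step",
    "build_multilevel",
    "read_timeseries",
    "read_manifest",
    "write_network",
    "read_network",
]

#: variance below this (sum of squared centred profile entries) is treated
#: as a degenerate, constant profile
_VAR_EPS = 1e-12

_SYM_TOL = 1e-12


class DegenerateInputError(ValueError):
    """Raised when an input is too degenerate to correlate (e.g. a
    constant ROI time course)."""


@dataclass
class ROITimeSeries:
    """One subject's ROI-averaged signal matrix.

    Attributes
    ----------
    subject_id : str
        Opaque subject identifier.
    data : ndarray, shape (T, R)
        Rows are time points, columns are ROIs.
    roi_labels : list of str, optional
        Region names, length ``R``.
    """

    subject_id: str
    data: np.ndarray
    roi_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be a 2-D matrix")
        t, r = self.data.shape
        if t < 3 or r < 3:
            raise ValueError(
                f"need at least 3 time points and 3 ROIs, got T={t}, R={r}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError(
                f"subject {self.subject_id!r}: time series contains NaN/Inf"
            )
        if self.roi_labels is not None and len(self.roi_labels) != r:
            raise ValueError(
                f"{len(self.roi_labels)} ROI labels for {r} ROIs"
            )

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass
class FCNetwork:
    """A level-tagged symmetric ``R x R`` connectivity matrix.

    Level 0 is the low-order (time-course correlation) network; level
    ``k >= 1`` is the ``k``-th high-order network.  The diagonal is fixed
    at 1 by convention so every level remains a valid correlation-like
    matrix; only the off-diagonal triangle carries information.
    """

    level: int
    matrix: np.ndarray
    subject_id: str
    roi_labels: list[str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.level < 0:
            raise ValueError("level must be >= 0")
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.all(np.isfinite(m)):
            raise ValueError("connectivity matrix contains NaN/Inf")
        if np.max(np.abs(m - m.T)) > _SYM_TOL:
            raise ValueError("connectivity matrix is not symmetric")
        if np.any(np.abs(np.diag(m) - 1.0) > _SYM_TOL):
            raise ValueError("diagonal entries must equal 1")
        if np.max(np.abs(m)) > 1.0 + _SYM_TOL:
            raise ValueError("entries must lie in [-1, 1]")

    @property
    def n_rois(self) -> int:
        return self.matrix.shape[0]


def _pearson_matrix(x: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlation of ``x`` (rows = observations)."""
    xc = x - x.mean(axis=0, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->j", xc, xc))
    corr = (xc.T @ xc) / np.outer(norms, norms)
    return corr


def _mirror_upper(m: np.ndarray) -> np.ndarray:
    """Copy the strict upper triangle onto the lower one and set the
    diagonal to 1, guaranteeing exact symmetry."""
    out = np.triu(m, 1)
    out = out + out.T
    np.fill_diagonal(out, 1.0)
    return out


def low_order_network(ts: ROITimeSeries) -> FCNetwork:
    """Pearson-correlation (low-order) FC network of one subject.

    Raises
    ------
    DegenerateInputError
        If any ROI time course has zero variance.
    """
    x = ts.data
    stds = x.std(axis=0)
    dead = np.flatnonzero(stds == 0.0)
    if dead.size:
        raise DegenerateInputError(
            f"subject {ts.subject_id!r}: zero-variance ROI column(s) "
            f"{dead.tolist()} — Pearson correlation undefined"
        )
    corr = _pearson_matrix(x)
    corr = np.clip(_mirror_upper(corr), -1.0, 1.0)
    return FCNetwork(level=0, matrix=corr, subject_id=ts.subject_id,
                     roi_labels=ts.roi_labels)


def high_order_step(net: FCNetwork) -> FCNetwork:
    """One "correlation of correlations" step: level ``k`` -> ``k + 1``.

    Entry ``(i, j)`` is the Pearson correlation between the FC profiles
    (rows) of regions ``i`` and ``j`` of the input matrix, with the
    entries at positions ``i`` and ``j`` removed from both rows before
    correlating.  A reduced profile with (numerically) zero variance
    yields entry 0 and a logged warning rather than NaN.

    Notes
    -----
    Implemented in closed form from full-row sufficient statistics: after
    centring each row by its full-row mean (Pearson correlation is
    shift-invariant per vector), the excluded entries are subtracted from
    the row sums, squared sums and cross products, so the whole matrix is
    computed without materialising the ``R(R-1)/2`` reduced profiles.
    """
    c = net.matrix
    r = c.shape[0]
    if r < 4:
        raise ValueError(
            "high-order step needs R >= 4 (reduced profiles must keep "
            ">= 2 entries)"
        )
    m = r - 2  # profile length after excluding positions i and j

    c0 = c - c.mean(axis=1, keepdims=True)
    d = np.diag(c0).copy()
    s = c0.sum(axis=1)
    q = np.einsum("ij,ij->i", c0, c0)
    p = c0 @ c0.T

    # For the pair (i, j): profile a = row i without entries i, j.
    sa = s[:, None] - d[:, None] - c0            # sa[i, j] = sum of a
    qa = q[:, None] - (d ** 2)[:, None] - c0 ** 2
    pab = p - d[:, None] * c0.T - c0 * d[None, :]

    cov = pab - sa * sa.T / m
    var = qa - sa ** 2 / m
    var = np.maximum(var, 0.0)

    # The subtraction form cancels catastrophically when a reduced
    # profile's variance is tiny relative to the row's scale; recompute
    # those few pairs exactly from the materialised reduced profiles.
    scale = np.maximum(q[:, None], 1e-300)
    risky = np.triu(var < 1e-3 * scale, 1) | np.triu((var < 1e-3 * scale).T, 1)
    for i, j in zip(*np.nonzero(risky)):
        keep = np.ones(r, dtype=bool)
        keep[[i, j]] = False
        a = c0[i, keep]
        b = c0[j, keep]
        a = a - a.mean()
        b = b - b.mean()
        var[i, j], var[j, i] = float(a @ a), float(b @ b)
        cov[i, j] = cov[j, i] = float(a @ b)

    degen = var <= _VAR_EPS
    denom = np.sqrt(var * var.T)
    bad = degen | degen.T
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(bad, 0.0, cov / np.where(bad, 1.0, denom))

    np.fill_diagonal(degen, False)
    if degen.any():
        rows = np.flatnonzero(degen.any(axis=1))
        logger.warning(
            "subject %s level %d: %d ROI profile(s) constant after "
            "exclusion (rows %s); affected entries set to 0",
            net.subject_id, net.level + 1, rows.size, rows.tolist(),
        )

    corr = np.clip(_mirror_upper(corr), -1.0, 1.0)
    return FCNetwork(level=net.level + 1, matrix=corr,
                     subject_id=net.subject_id, roi_labels=net.roi_labels)


def build_multilevel(ts: ROITimeSeries, t: int) -> list[FCNetwork]:
    """Build the level hierarchy ``[LON, HON-1, ..., HON-t]``.

    ``t = 0`` returns only the low-order network.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    nets = [low_order_network(ts)]
    for _ in range(t):
        nets.append(high_order_step(nets[-1]))
    return nets


# ---------------------------------------------------------------------------
# file formats: delimited-text time series, manifests, network matrices
# ---------------------------------------------------------------------------

def _sniff_delimiter(line: str) -> str:
    return "\t" if line.count("\t") >= line.count(",") and "\t" in line else ","


def _is_numeric_row(cells: list[str]) -> bool:
    try:
        for cell in cells:
            float(cell)
    except ValueError:
        return False
    return True


def read_timeseries(path: str | Path, subject_id: str | None = None) -> ROITimeSeries:
    """Read one subject's ``T x R`` matrix from comma- or tab-delimited
    text.  An optional single header row of ROI labels is detected by its
    first row being non-numeric.  Malformed cells raise a ``ValueError``
    naming the file, row and column.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty time-series file")
    delim = _sniff_delimiter(lines[0])
    first = [c.strip() for c in lines[0].split(delim)]
    labels: list[str] | None = None
    start = 0
    if not _is_numeric_row(first):
        labels = first
        start = 1
    rows: list[list[float]] = []
    ncol: int | None = None
    for irow, ln in enumerate(lines[start:], start=start + 1):
        cells = [c.strip() for c in ln.split(delim)]
        if ncol is None:
            ncol = len(cells)
        elif len(cells) != ncol:
            raise ValueError(
                f"{path}: row {irow} has {len(cells)} columns, expected {ncol}"
            )
        row = []
        for icol, cell in enumerate(cells, start=1):
            try:
                row.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell at row {irow}, column {icol}: "
                    f"{cell!r}"
                ) from None
        rows.append(row)
    sid = subject_id if subject_id is not None else path.stem
    return ROITimeSeries(subject_id=sid, data=np.array(rows), roi_labels=labels)


def read_manifest(path: str | Path) -> list[tuple[str, Path, int]]:
    """Read a cohort manifest CSV with columns subject_id, file, label.

    ``file`` paths are resolved relative to the manifest's directory.
    Labels must be +1 / -1.  Returns a list of (subject_id, path, label).
    """
    path = Path(path)
    entries: list[tuple[str, Path, int]] = []
    lines = [ln for ln in path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty manifest")
    header = [c.strip() for c in lines[0].split(",")]
    required = {"subject_id", "file", "label"}
    if not required.issubset(header):
        raise ValueError(
            f"{path}: manifest header must contain {sorted(required)}, "
            f"got {header}"
        )
    idx = {name: header.index(name) for name in required}
    for ln in lines[1:]:
        cells = [c.strip() for c in ln.split(",")]
        label = int(cells[idx["label"]])
        if label not in (1, -1):
            raise ValueError(f"{path}: label must be +1/-1, got {label}")
        entries.append(
            (cells[idx["subject_id"]], path.parent / cells[idx["file"]], label)
        )
    return entries


def write_network(net: FCNetwork, path: str | Path) -> None:
    """Write a network matrix as delimited text with a metadata sidecar
    line (``# subject=... level=... R=...``)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# subject={net.subject_id} level={net.level} R={net.n_rois}\n")
        for row in net.matrix:
            fh.write(",".join(format(v, ".17g") for v in row) + "\n")


def read_network(path: str | Path) -> FCNetwork:
    """Inverse of :func:`write_network`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise ValueError(f"{path}: missing metadata line")
    meta = dict(tok.split("=", 1) for tok in lines[0][1:].split())
    matrix = np.array([[float(c) for c in ln.split(",")]
                       for ln in lines[1:] if ln.strip()])
    return FCNetwork(level=int(meta["level"]), matrix=matrix,
                     subject_id=meta["subject"])
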