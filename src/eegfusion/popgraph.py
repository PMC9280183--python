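"""Population graph: subjects as nodes, edges combining imaging-feature and
phenotypic similarity.

The edge weight between subjects v and w is

    W(v, w) = sim(A_v, A_w) * sum_h gamma(M_h(v), M_h(w))

where ``sim`` is a Gaussian kernel on a feature distance,
``sim = exp(-rho^2 / (2 sigma^2))``, and each phenotype h contributes
gamma = 1 when the subjects agree (Kronecker delta for qualitative
phenotypes such as gender; a unit step |difference| < theta for
quantitative ones such as age) and 0 otherwise.

The feature distance rho is the correlation distance 1 - Pearson r between
the subjects' flattened fused-image vectors, clipped to [0, 1]: identical
images give rho = 0 and maximal similarity, uncorrelated images rho = 1.
A zero-variance feature vector has no defined correlation; its distance is
set to 1 (maximally dissimilar) and a warning is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PhenotypeRecord",
    "GraphConfig",
    "PopulationGraph",
    "PopGraphError",
    "correlation_distance",
    "feature_similarity",
    "phenotype_similarity",
    "build_adjacency",
    "read_phenotypes_csv",
    "write_phenotypes_csv",
    "save_graph",
    "load_graph",
]

logger = logging.getLogger(__name__)

GENDERS = ("male", "female")


class PopGraphError(ValueError):
    """Raised for invalid phenotype or graph configuration input."""


@dataclass(frozen=True)
class PhenotypeRecord:
    subject_id: str
    gender: str
    age: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.age < 0:
            raise PopGraphError(f"negative age for subject {self.subject_id!r}")
        if self.gender not in GENDERS:
            raise PopGraphError(
                f"gender {self.gender!r} not in declared set {GENDERS}"
            )

    def value(self, phenotype: str):
        if phenotype not in ("gender", "age"):
            raise PopGraphError(f"unknown phenotype {phenotype!r}")
        return getattr(self, phenotype)


@dataclass(frozen=True)
class GraphConfig:
    """Kernel width, quantitative threshold, and phenotype kinds.

    ``sigma`` is the Gaussian kernel width (same units as the feature
    distance); ``theta`` the quantitative agreement threshold in the
    phenotype's units (years for age).
    """

    sigma: float = 1.0
    theta: float = 2.0
    phenotype_kinds: dict[str, str] = field(
        default_factory=lambda: {"gender": "qualitative", "age": "quantitative"}
    )

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise PopGraphError("sigma must be positive")
        if self.theta <= 0:
            raise PopGraphError("theta must be positive")
        for name, kind in self.phenotype_kinds.items():
            if kind not in ("qualitative", "quantitative"):
                raise PopGraphError(f"phenotype {name!r} has unknown kind {kind!r}")


@dataclass(frozen=True)
class PopulationGraph:
    """Symmetric non-negative adjacency matrix over an ordered subject list."""

    subjects: tuple[str, ...]
    W: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "subjects", tuple(self.subjects))
        n = len(self.subjects)
        if W.shape != (n, n):
            raise PopGraphError(f"adjacency must be {n}x{n}, got {W.shape}")
        if not np.allclose(W, W.T, atol=1e-12):
            raise PopGraphError("adjacency matrix is not symmetric")
        if np.any(W < 0):
            raise PopGraphError("adjacency entries must be non-negative")
        if np.any(np.abs(np.diag(W)) > 1e-12):
            raise PopGraphError("self-edges are excluded; diagonal must be zero")


def correlation_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 - Pearson r between two vectors, clipped to [0, 1].

    Identical (or perfectly correlated) vectors give 0; anticorrelation is
    clipped to 1 so the distance respects the kernel's (0, 1] range. A
    constant vector has undefined correlation and maps to distance 1.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise PopGraphError("feature vectors must have equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise PopGraphError("non-finite feature values")
    if np.array_equal(x, y):
        return 0.0
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        logger.warning("zero-variance feature vector; correlation distance set to 1")
        return 1.0
    r = float(np.corrcoef(x, y)[0, 1])
    return float(np.clip(1.0 - r, 0.0, 1.0))


def feature_similarity(x_v: np.ndarray, x_w: np.ndarray, sigma: float = 1.0) -> float:
    """Gaussian kernel exp(-rho^2 / (2 sigma^2)) on the correlation distance."""
    if sigma <= 0:
        raise PopGraphError("sigma must be positive")
    rho = correlation_distance(x_v, x_w)
    return float(np.exp(-(rho**2) / (2.0 * sigma**2)))


def phenotype_similarity(
    a: PhenotypeRecord, b: PhenotypeRecord, phenotype: str, cfg: GraphConfig
) -> int:
    """Binary phenotype agreement: Kronecker delta or thresholded difference."""
    if phenotype not in cfg.phenotype_kinds:
        raise PopGraphError(f"phenotype {phenotype!r} not declared in config")
    try:
        va, vb = a.value(phenotype), b.value(phenotype)
    except PopGraphError:
        logger.warning("missing phenotype %r; term contributes 0", phenotype)
        return 0
    if va is None or vb is None or (isinstance(va, float) and np.isnan(va)):
        logger.warning("missing phenotype %r value; term contributes 0", phenotype)
        return 0
    if cfg.phenotype_kinds[phenotype] == "qualitative":
        return int(va == vb)
    return int(abs(float(va) - float(vb)) < cfg.theta)


def build_adjacency(
    features: Mapping[str, np.ndarray] | Sequence[np.ndarray],
    phenos: Sequence[PhenotypeRecord],
    cfg: GraphConfig | None = None,
) -> PopulationGraph:
    """Assemble the population adjacency matrix.

    ``features`` maps subject_id to a flattened feature vector (or is a
    sequence aligned with ``phenos``). Off-diagonal entries multiply the
    Gaussian feature kernel by the summed phenotype agreements; the
    diagonal is zero.
    """
    cfg = cfg or GraphConfig()
    ids = [p.subject_id for p in phenos]
    if len(set(ids)) != len(ids):
        raise PopGraphError("duplicate subject ids in phenotype records")
    if len(ids) < 2:
        raise PopGraphError("need at least two subjects")
    if isinstance(features, Mapping):
        missing = [i for i in ids if i not in features]
        if missing:
            raise PopGraphError(f"no features for subjects {missing}")
        vecs = [np.asarray(features[i], dtype=float).ravel() for i in ids]
    else:
        if len(features) != len(ids):
            raise PopGraphError("features and phenotypes are not aligned")
        vecs = [np.asarray(f, dtype=float).ravel() for f in features]

    n = len(ids)
    phenotypes = list(cfg.phenotype_kinds)
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sim = feature_similarity(vecs[i], vecs[j], cfg.sigma)
            gam = sum(
                phenotype_similarity(phenos[i], phenos[j], h, cfg) for h in phenotypes
            )
            W[i, j] = W[j, i] = sim * gam
    return PopulationGraph(tuple(ids), W)


# --- I/O -------------------------------------------------------------------

def read_phenotypes_csv(path: str | Path) -> list[PhenotypeRecord]:
    frame = pd.read_csv(path, dtype={"subject_id": str})
    needed = {"subject_id", "gender", "age"}
    missing = needed - set(frame.columns)
    if missing:
        raise PopGraphError(f"phenotype CSV missing columns {sorted(missing)}")
    label_col = frame["label"] if "label" in frame.columns else [""] * len(frame)
    return [
        PhenotypeRecord(str(s), str(g), float(a), str(l))
        for s, g, a, l in zip(frame["subject_id"], frame["gender"], frame["age"], label_col)
    ]


def write_phenotypes_csv(phenos: Sequence[PhenotypeRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in phenos],
            "gender": [p.gender for p in phenos],
            "age": [p.age for p in phenos],
            "label": [p.label for p in phenos],
        }
    ).to_csv(path, index=False)


def save_graph(graph: PopulationGraph, matrix_path: str | Path, edges_path: str | Path | None = None) -> None:
    """Export the adjacency as a labeled matrix text file and an edge list."""
    header = " ".join(graph.subjects)
    np.savetxt(matrix_path, graph.W, fmt="%.12g", header=header)
    if edges_path is not None:
        with open(edges_path, "w") as fh:
            fh.write("v w weight\n")
            n = len(graph.subjects)
            for i in range(n):
                for j in range(i + 1, n):
                    if graph.W[i, j] > 0:
                        fh.write(f"{graph.subjects[i]} {graph.subjects[j]} {graph.W[i, j]:.12g}\n")


def load_graph(matrix_path: str | Path) -> PopulationGraph:
    with open(matrix_path) as fh:
        first = fh.readline()
    subjects = first.lstrip("#").split()
    W = np.loadtxt(matrix_path)
    return PopulationGraph(tuple(subjects), np.atleast_2d(W))
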