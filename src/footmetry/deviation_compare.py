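"""Signed surface deviations between meshes and tolerance-band summaries.

Deviations are sampled at the test-mesh vertices: for each vertex the nearest
point on the reference surface is found and the distance is signed by the
nearest reference face's normal (positive = outside).  Summaries report the
fractions of samples inside / above / below a symmetric tolerance band
(|d| = tol counts as in-tolerance).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from ._geometry import signed_distance_to_mesh
from .errors import InvalidDesignError, MeshFormatError
from .mesh_io import TriangleMesh, write_triangle_mesh

__all__ = [
    "DeviationField",
    "ToleranceSummary",
    "signed_deviation",
    "tolerance_summary",
    "consistency_matrix",
    "write_field_csv",
    "write_field_ply",
]


@dataclass
class DeviationField:
    """Per-sample signed distances of a test mesh to a reference surface."""

    points: np.ndarray
    distances: np.ndarray
    reference_name: str = ""
    test_name: str = ""

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        self.distances = np.asarray(self.distances, dtype=np.float64).reshape(-1)
        if len(self.points) != len(self.distances):
            raise ValueError("one distance per sample point required")
        if not np.all(np.isfinite(self.distances)):
            raise ValueError("deviation field contains non-finite distances")


@dataclass
class ToleranceSummary:
    """In/over/under fractions for a symmetric deviation tolerance band."""

    tolerance: float
    fraction_in: float
    fraction_over: float
    fraction_under: float
    mean: float
    sd: float
    max_abs: float
    reference_name: str = ""
    test_name: str = ""

    def to_rows(self) -> Sequence[Tuple[str, float, str]]:
        return [
            ("tolerance", self.tolerance, "mm"),
            ("fraction_in", self.fraction_in, "ratio"),
            ("fraction_over", self.fraction_over, "ratio"),
            ("fraction_under", self.fraction_under, "ratio"),
            ("mean_deviation", self.mean, "mm"),
            ("sd_deviation", self.sd, "mm"),
            ("max_abs_deviation", self.max_abs, "mm"),
        ]

    def meta(self) -> Mapping[str, object]:
        return {"reference": self.reference_name, "test": self.test_name}


def signed_deviation(test: TriangleMesh, reference: TriangleMesh) -> DeviationField:
    """Signed distance from every test vertex to the reference surface."""
    if test.n_faces == 0 or reference.n_faces == 0:
        raise MeshFormatError("cannot compare meshes with zero faces")
    d = signed_distance_to_mesh(test.vertices, reference.vertices, reference.faces)
    return DeviationField(
        points=test.vertices.copy(),
        distances=d,
        reference_name=reference.name,
        test_name=test.name,
    )


def tolerance_summary(field: DeviationField, tolerance: float = 1.0) -> ToleranceSummary:
    """Summarise a deviation field against a symmetric +/- tolerance."""
    if tolerance <= 0:
        raise InvalidDesignError(f"tolerance must be positive, got {tolerance}")
    d = field.distances
    n = len(d)
    if n == 0:
        raise ValueError("empty deviation field")
    over = float(np.count_nonzero(d > tolerance)) / n
    under = float(np.count_nonzero(d < -tolerance)) / n
    return ToleranceSummary(
        tolerance=float(tolerance),
        fraction_in=1.0 - over - under,
        fraction_over=over,
        fraction_under=under,
        mean=float(d.mean()),
        sd=float(d.std(ddof=1)) if n > 1 else 0.0,
        max_abs=float(np.abs(d).max()),
        reference_name=field.reference_name,
        test_name=field.test_name,
    )


def consistency_matrix(
    designs: Sequence[TriangleMesh],
    groups: Mapping[str, Sequence[Tuple[int, int]]],
    tolerance: float = 1.0,
) -> pd.DataFrame:
    """Mean +/- SD percentage in-tolerance per comparison category.

    ``groups`` maps a category name to (test_index, reference_index) pairs
    into ``designs``.  Categories with no pairs raise
    :class:`InvalidDesignError`.
    """
    if len(designs) < 2:
        raise InvalidDesignError("need at least two designs to compare")
    rows = []
    for category, pairs in groups.items():
        pairs = list(pairs)
        if not pairs:
            raise InvalidDesignError(f"group {category!r} has no comparison pairs")
        pct = []
        for it, ir in pairs:
            field = signed_deviation(designs[it], designs[ir])
            summary = tolerance_summary(field, tolerance)
            pct.append(summary.fraction_in * 100.0)
        pct_arr = np.asarray(pct)
        rows.append(
            {
                "category": category,
                "n_pairs": len(pct),
                "mean_pct_in": float(pct_arr.mean()),
                "sd_pct_in": float(pct_arr.std(ddof=1)) if len(pct) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def write_field_csv(field: DeviationField, path) -> None:
    """Export a deviation field as x,y,z,distance CSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x", "y", "z", "distance"])
        for p, d in zip(field.points, field.distances):
            w.writerow([f"{p[0]:.6f}", f"{p[1]:.6f}", f"{p[2]:.6f}", f"{d:.6f}"])


def write_field_ply(field: DeviationField, test: TriangleMesh, path) -> None:
    """Export the test mesh with the deviation as a per-vertex PLY scalar."""
    if len(field.distances) != test.n_vertices:
        raise ValueError("field was not sampled at this mesh's vertices")
    write_triangle_mesh(
        test, path, fmt="ply", vertex_scalars={"deviation": field.distances}
    )
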