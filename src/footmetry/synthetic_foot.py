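"""Parametric foot-like meshes with ground-truth landmarks, weight-bearing
deformation, rater landmark-noise models and full simulated reliability
studies.

The phantom is a closed loft of flat-soled cross-sections (flat bottom edge
plus a superelliptical dorsal arc) along Y, with a tall hindfoot "leg stub"
carrying the malleoli and a medial Gaussian arch concavity whose apex height
equals the ``arch_height`` parameter exactly.  Ground truth by construction:

* the plantar landmarks HEEL/MT1/MT5 lie on the sole at z = 0;
* MT1/MT5 sit at ``x = -/+ forefoot_width / 2``;
* the trace width at the heel landmark equals ``heel_width``;
* the arch landmark sits at ``z = arch_height``;
* the bounding box below the malleoli spans ``length`` along Y.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .errors import InvalidDesignError
from .mesh_io import LANDMARK_IDS, MEASUREMENT_NAMES, LandmarkSet, TriangleMesh
from .morphometry import measure_foot
from .registration import RigidTransform

__all__ = [
    "FootParams",
    "RaterModel",
    "StudyDesign",
    "CONDITION_LOADS",
    "generate_foot",
    "apply_weight_bearing",
    "perturb_landmarks",
    "sample_foot_params",
    "default_raters",
    "generate_study_scans",
    "measure_panel",
    "simulate_reliability_study",
    "random_rigid_transform",
]

#: Fraction-of-length stations for anatomical features.
_Y_HEEL = 0.10
_Y_MALLEOLI = 0.18
_Y_MT = 0.72

#: Dorsal-arc superellipse exponent.
_ARC_EXP = 2.5

#: Load factor per weight-bearing condition.
CONDITION_LOADS: Dict[str, float] = {"NWB": 0.0, "PWB": 0.5, "HWB": 1.0}

_SeedLike = Union[int, np.random.SeedSequence, np.random.Generator]


@dataclass(frozen=True)
class FootParams:
    """Shape parameters of the phantom foot (millimetres unless noted)."""

    length: float = 250.0
    forefoot_width: float = 95.0
    heel_width: float = 62.0
    arch_height: float = 18.0
    arch_apex_y: float = 0.42  # fraction of length
    instep_height: float = 60.0
    toe_taper: float = 0.5  # 0..1
    leg_stub_height: float = 30.0

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise InvalidDesignError(f"{f.name} must be finite and non-negative")
        if min(self.length, self.forefoot_width, self.heel_width,
               self.instep_height, self.leg_stub_height) <= 0:
            raise InvalidDesignError("principal dimensions must be positive")
        if self.arch_height >= self.instep_height:
            raise InvalidDesignError("arch_height must be below instep_height")
        if not (0.2 <= self.arch_apex_y <= 0.6):
            raise InvalidDesignError("arch_apex_y must lie in [0.2, 0.6]")
        if not (0.0 <= self.toe_taper <= 1.0):
            raise InvalidDesignError("toe_taper must lie in [0, 1]")


def _profiles(p: FootParams):
    """Half-width and height profiles along normalised y, via monotone PCHIP."""
    wf2 = p.forefoot_width / 2.0
    wh2 = p.heel_width / 2.0
    waist = max(0.60 * wf2, 0.90 * wh2)
    tip = max(1.0, wf2 * (0.45 - 0.25 * p.toe_taper))
    w_knots = [
        (0.00, 0.30 * wh2),
        (_Y_HEEL, wh2),
        (_Y_MALLEOLI, 0.97 * wh2),
        (0.42, waist),
        (_Y_MT, wf2),
        (0.88, 0.90 * wf2),
        (1.00, tip),
    ]
    ankle_base = 1.10 * p.instep_height
    ankle_top = ankle_base + p.leg_stub_height
    h_knots = [
        (0.00, 0.50 * ankle_top),
        (0.06, 0.85 * ankle_top),
        (0.12, ankle_top),
        (0.24, ankle_top),
        (0.38, 1.05 * p.instep_height),
        (0.55, 0.88 * p.instep_height),
        (_Y_MT, 0.52 * p.instep_height),
        (0.90, 0.30 * p.instep_height),
        (1.00, 0.12 * p.instep_height),
    ]
    w = PchipInterpolator(*zip(*w_knots))
    h = PchipInterpolator(*zip(*h_knots))
    return w, h, ankle_base, ankle_top


def _section_ring(
    w: float, h: float, n_bottom: int, n_arc: int
) -> np.ndarray:
    """Cross-section outline in (x, z): flat sole plus superelliptical arc."""
    xs = np.linspace(-w, w, n_bottom + 1)
    bottom = np.column_stack([xs, np.zeros(n_bottom + 1)])
    theta = np.linspace(0.0, np.pi, n_arc + 2)[1:-1]
    cx = np.cos(theta)
    arc_x = w * np.sign(cx) * np.abs(cx) ** (2.0 / _ARC_EXP)
    arc_z = h * np.sin(theta) ** (2.0 / _ARC_EXP)
    arc = np.column_stack([arc_x, arc_z])  # runs from +w back to -w over the top
    return np.vstack([bottom, arc])


def _arch_lift(
    x: np.ndarray, y: np.ndarray, z: np.ndarray, p: FootParams, w_arch: float
) -> np.ndarray:
    """Upward sole displacement creating the medial arch concavity."""
    if p.arch_height == 0:
        return np.zeros_like(np.broadcast_arrays(x, y, z)[0], dtype=np.float64)
    y_a = p.arch_apex_y * p.length
    x_c = -0.70 * w_arch
    sig_y = 0.09 * p.length
    sig_x = 0.35 * w_arch
    z_s = 0.60 * p.instep_height
    g = np.exp(-0.5 * ((y - y_a) / sig_y) ** 2)
    b = np.exp(-0.5 * ((x - x_c) / sig_x) ** 2)
    s = np.clip(1.0 - z / z_s, 0.0, None) ** 2
    return p.arch_height * g * b * s


def _build(params: FootParams, resolution: int) -> Tuple[np.ndarray, np.ndarray, Dict[str, np.ndarray]]:
    L = params.length
    w_fn, h_fn, ankle_base, ankle_top = _profiles(params)

    n_bottom = max(6, resolution // 3)
    n_arc = max(10, resolution - n_bottom)
    nr = n_bottom + 1 + n_arc

    base = np.linspace(0.004, 0.996, resolution)
    extra = np.array([_Y_HEEL, _Y_MALLEOLI, params.arch_apex_y, _Y_MT])
    stations = np.unique(np.round(np.concatenate([base, extra]), 9)) * L

    rings = []
    for y in stations:
        ring = _section_ring(float(w_fn(y / L)), float(h_fn(y / L)), n_bottom, n_arc)
        rings.append(
            np.column_stack([ring[:, 0], np.full(nr, y), ring[:, 1]])
        )
    rear_apex = np.array([[0.0, 0.0, 0.5 * float(h_fn(0.0))]])
    toe_apex = np.array([[0.0, L, 0.5 * float(h_fn(1.0))]])
    verts = np.vstack([rear_apex] + rings + [toe_apex])

    faces: List[List[int]] = []
    for i in range(nr):  # rear cap fan
        faces.append([0, 1 + i, 1 + (i + 1) % nr])
    for j in range(len(stations) - 1):
        a0 = 1 + j * nr
        b0 = 1 + (j + 1) * nr
        for i in range(nr):
            i2 = (i + 1) % nr
            faces.append([a0 + i, a0 + i2, b0 + i])
            faces.append([a0 + i2, b0 + i2, b0 + i])
    toe = len(verts) - 1
    last = 1 + (len(stations) - 1) * nr
    for i in range(nr):  # toe cap fan
        faces.append([toe, last + (i + 1) % nr, last + i])
    faces_arr = np.asarray(faces, dtype=np.int64)

    # medial arch concavity
    w_arch = float(w_fn(params.arch_apex_y))
    verts[:, 2] += _arch_lift(verts[:, 0], verts[:, 1], verts[:, 2], params, w_arch)

    # outward orientation
    tri = verts[faces_arr]
    vol = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0
    if vol < 0:
        faces_arr = faces_arr[:, [0, 2, 1]]

    # ground-truth landmarks
    wf2 = params.forefoot_width / 2.0
    y_mt = _Y_MT * L
    y_heel = _Y_HEEL * L
    y_mal = _Y_MALLEOLI * L
    w_mal = float(w_fn(_Y_MALLEOLI))
    h_mal = float(h_fn(_Y_MALLEOLI))

    def arc_x_at(zq: float, h: float, w: float) -> float:
        s = np.clip((zq / h) ** (_ARC_EXP / 2.0), 0.0, 1.0)
        c = np.sqrt(max(0.0, 1.0 - s * s))
        return w * c ** (2.0 / _ARC_EXP)

    z_med = ankle_base
    z_lat = max(0.5 * ankle_base, ankle_base - 4.0)
    landmarks = {
        "HEEL": np.array([0.0, y_heel, 0.0]),
        "MT1": np.array([-wf2, y_mt, 0.0]),
        "MT5": np.array([wf2, y_mt, 0.0]),
        "ARCH": np.array(
            [-0.70 * w_arch, params.arch_apex_y * L, params.arch_height]
        ),
        "MED_MAL": np.array([-arc_x_at(z_med, h_mal, w_mal), y_mal, z_med]),
        "LAT_MAL": np.array([arc_x_at(z_lat, h_mal, w_mal), y_mal, z_lat]),
    }
    return verts, faces_arr, landmarks


def generate_foot(
    params: FootParams, resolution: int = 48, seed: int = 0
) -> Tuple[TriangleMesh, LandmarkSet]:
    """Generate a closed manifold phantom foot with ground-truth landmarks.

    Deterministic for a given (params, resolution, seed); the seed is recorded
    in the mesh provenance and reserved for future stochastic surface detail.
    """
    params.validate()
    if resolution < 16:
        raise InvalidDesignError("resolution must be at least 16")
    verts, faces, lm = _build(params, resolution)
    mesh = TriangleMesh(
        verts,
        faces,
        name=f"synthfoot-L{params.length:.0f}-r{resolution}-s{seed}",
        meta={"params": params, "resolution": resolution, "seed": seed, "load": 0.0},
    )
    return mesh, LandmarkSet({k: v for k, v in lm.items()}, source="guided")


def loaded_params(params: FootParams, load: float) -> FootParams:
    """Parameters after weight bearing: arch drops 50%, widths gain 5% at full load."""
    return replace(
        params,
        arch_height=params.arch_height * (1.0 - 0.5 * load),
        forefoot_width=params.forefoot_width * (1.0 + 0.05 * load),
        heel_width=params.heel_width * (1.0 + 0.05 * load),
    )


def apply_weight_bearing(
    mesh: TriangleMesh,
    landmarks: LandmarkSet,
    params: FootParams,
    load: float,
    resolution: Optional[int] = None,
) -> Tuple[TriangleMesh, LandmarkSet]:
    """Deform a generated foot for a weight-bearing load in [0, 1].

    Implemented by re-evaluating the analytic shape with load-adjusted
    parameters, which moves mesh and landmarks consistently; ``load = 0`` is
    the identity.
    """
    if not (0.0 <= load <= 1.0):
        raise InvalidDesignError(f"load must lie in [0, 1], got {load}")
    res = resolution if resolution is not None else mesh.meta.get("resolution", 48)
    seed = mesh.meta.get("seed", 0)
    out_mesh, out_lm = generate_foot(loaded_params(params, load), res, seed)
    out_mesh.name = mesh.name
    out_mesh.meta["load"] = load
    out_lm = LandmarkSet(out_lm.points, side=landmarks.side, source=landmarks.source)
    return out_mesh, out_lm


# ---------------------------------------------------------------------------
# rater noise models
# ---------------------------------------------------------------------------

#: Surface-normal direction per landmark for tangential jitter.
_CANONICAL_NORMALS: Dict[str, np.ndarray] = {
    "HEEL": np.array([0.0, 0.0, 1.0]),
    "MT1": np.array([0.0, 0.0, 1.0]),
    "MT5": np.array([0.0, 0.0, 1.0]),
    "ARCH": np.array([-1.0, 0.0, 0.0]),
    "MED_MAL": np.array([-1.0, 0.0, 0.0]),
    "LAT_MAL": np.array([1.0, 0.0, 0.0]),
}

_PLANTAR_IDS = ("HEEL", "MT1", "MT5")


@dataclass
class RaterModel:
    """Landmark placement noise: per-landmark jitter sigma and bias."""

    mode: str  # "guided" | "scan_derived"
    sigma: Mapping[str, float]
    bias: Mapping[str, np.ndarray] = field(default_factory=dict)
    tangential_only: bool = False
    name: str = ""

    def __post_init__(self):
        if self.mode not in ("guided", "scan_derived"):
            raise InvalidDesignError(f"unknown rater mode {self.mode!r}")
        if not isinstance(self.sigma, Mapping):
            self.sigma = {lid: float(self.sigma) for lid in LANDMARK_IDS}
        if any(s < 0 for s in self.sigma.values()):
            raise InvalidDesignError("sigma must be non-negative")
        self.bias = {
            lid: np.asarray(v, dtype=np.float64).reshape(3)
            for lid, v in self.bias.items()
        }

    @classmethod
    def guided(cls, sigma: float = 0.8, name: str = "") -> "RaterModel":
        """Palpation-guided rater: small unbiased jitter along the skin surface."""
        return cls(mode="guided", sigma=sigma, tangential_only=True, name=name)

    @classmethod
    def scan_derived(
        cls,
        seed: int,
        sigma_plantar: float = 3.5,
        sigma_dorsal: float = 2.0,
        bias_plantar: float = 2.5,
        bias_dorsal: float = 1.0,
        name: str = "",
    ) -> "RaterModel":
        """Scan-derived rater: larger jitter plus a per-rater systematic bias.

        Plantar landmarks get the larger sigma/bias (they lack visual cues);
        plantar biases are drawn tangential to the sole.
        """
        rng = np.random.default_rng(seed)
        sigma = {
            lid: (sigma_plantar if lid in _PLANTAR_IDS else sigma_dorsal)
            for lid in LANDMARK_IDS
        }
        bias = {}
        for lid in LANDMARK_IDS:
            mag = bias_plantar if lid in _PLANTAR_IDS else bias_dorsal
            v = rng.standard_normal(3)
            if lid in _PLANTAR_IDS:
                v[2] = 0.0
            norm = np.linalg.norm(v)
            bias[lid] = (v / norm * mag) if norm > 0 else np.zeros(3)
        return cls(
            mode="scan_derived", sigma=sigma, bias=bias, tangential_only=True,
            name=name,
        )


def perturb_landmarks(
    landmarks: LandmarkSet, model: RaterModel, seed: _SeedLike
) -> LandmarkSet:
    """Displace each landmark by its bias plus Gaussian jitter (seeded)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    points: Dict[str, np.ndarray] = {}
    for lid in LANDMARK_IDS:
        if lid not in landmarks:
            continue
        sigma = float(model.sigma.get(lid, 0.0))
        jitter = sigma * rng.standard_normal(3)
        if model.tangential_only:
            nrm = _CANONICAL_NORMALS[lid]
            jitter = jitter - np.dot(jitter, nrm) * nrm
        delta = np.asarray(model.bias.get(lid, np.zeros(3))) + jitter
        points[lid] = landmarks[lid] + delta
    return LandmarkSet(points, side=landmarks.side, source=model.mode)


def default_raters(
    mode: str, n: int = 3, seed: int = 0, sigma: Optional[float] = None
) -> List[RaterModel]:
    """Build ``n`` rater models named A, B, C, ... for a landmarking mode."""
    names = [chr(ord("A") + i) for i in range(n)]
    if mode == "guided":
        s = 0.8 if sigma is None else sigma
        return [RaterModel.guided(sigma=s, name=nm) for nm in names]
    if mode == "scan_derived":
        s = 3.5 if sigma is None else sigma
        return [
            RaterModel.scan_derived(
                seed=seed + 1000 * i, sigma_plantar=s, sigma_dorsal=0.6 * s, name=nm
            )
            for i, nm in enumerate(names)
        ]
    raise InvalidDesignError(f"unknown rater mode {mode!r}")


# ---------------------------------------------------------------------------
# study simulation
# ---------------------------------------------------------------------------


@dataclass
class StudyDesign:
    """Reliability-study layout (subjects x feet x conditions x raters x reps)."""

    n_subjects: int
    feet_per_subject: int = 2
    conditions: Tuple[str, ...] = ("NWB",)
    raters: Tuple[RaterModel, ...] = ()
    repetitions: int = 1
    seed: int = 0
    resolution: int = 32

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise InvalidDesignError("n_subjects must be >= 1")
        if self.feet_per_subject not in (1, 2):
            raise InvalidDesignError("feet_per_subject must be 1 or 2")
        if self.repetitions < 1:
            raise InvalidDesignError("repetitions must be >= 1")
        if not self.conditions:
            raise InvalidDesignError("at least one condition required")
        for c in self.conditions:
            if c not in CONDITION_LOADS:
                raise InvalidDesignError(f"unknown condition {c!r}")
        if not self.raters:
            raise InvalidDesignError("at least one rater model required")


def sample_foot_params(rng: np.random.Generator) -> FootParams:
    """Default population sampler for phantom feet."""
    return FootParams(
        length=float(np.clip(rng.normal(250.0, 15.0), 200.0, 300.0)),
        forefoot_width=float(np.clip(rng.normal(95.0, 6.0), 75.0, 115.0)),
        heel_width=float(np.clip(rng.normal(62.0, 4.0), 48.0, 78.0)),
        arch_height=float(np.clip(rng.normal(18.0, 4.0), 8.0, 30.0)),
        arch_apex_y=float(rng.uniform(0.38, 0.48)),
        instep_height=float(np.clip(rng.normal(60.0, 4.0), 48.0, 75.0)),
        toe_taper=float(rng.uniform(0.3, 0.7)),
        leg_stub_height=30.0,
    )


def generate_study_scans(
    design: StudyDesign,
    params_sampler: Optional[Callable[[np.random.Generator], FootParams]] = None,
) -> List[dict]:
    """Generate one scan record per subject x foot x condition."""
    design.validate()
    sampler = params_sampler or sample_foot_params
    rng = np.random.default_rng(design.seed)
    scans: List[dict] = []
    sides = ("L", "R")[: design.feet_per_subject]
    for s in range(design.n_subjects):
        for side in sides:
            params = sampler(rng)
            base_mesh, base_lm = generate_foot(
                params, design.resolution, seed=design.seed
            )
            for condition in design.conditions:
                load = CONDITION_LOADS[condition]
                if load == 0.0:
                    mesh, lm = base_mesh, base_lm
                else:
                    mesh, lm = apply_weight_bearing(
                        base_mesh, base_lm, params, load
                    )
                scans.append(
                    {
                        "subject": f"P{s + 1:02d}{side}",
                        "condition": condition,
                        "load": load,
                        "mesh": mesh,
                        "landmarks": lm,
                        "params": params,
                    }
                )
    return scans


def measure_panel(
    scans: Sequence[dict],
    raters: Sequence[RaterModel],
    repetitions: int,
    seed: int,
) -> pd.DataFrame:
    """Apply rater noise and measure every scan x rater x repetition cell."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(scans) * len(raters) * repetitions)
    rows = []
    idx = 0
    for scan in scans:
        for j, rater in enumerate(raters):
            rater_id = rater.name or chr(ord("A") + j)
            for rep in range(1, repetitions + 1):
                lm = perturb_landmarks(scan["landmarks"], rater, children[idx])
                idx += 1
                report = measure_foot(
                    scan["mesh"], lm, condition=scan["condition"]
                )
                for name in MEASUREMENT_NAMES:
                    rows.append(
                        {
                            "subject": scan["subject"],
                            "rater": rater_id,
                            "repetition": rep,
                            "condition": scan["condition"],
                            "measurement": name,
                            "value": report.values[name],
                        }
                    )
    return pd.DataFrame(rows)


def simulate_reliability_study(
    design: StudyDesign,
    params_sampler: Optional[Callable[[np.random.Generator], FootParams]] = None,
) -> Tuple[pd.DataFrame, dict]:
    """Run the full simulated study; returns (long-format panel, provenance)."""
    scans = generate_study_scans(design, params_sampler)
    panel = measure_panel(scans, design.raters, design.repetitions, design.seed)
    provenance = {
        "seed": design.seed,
        "n_subjects": design.n_subjects,
        "feet_per_subject": design.feet_per_subject,
        "conditions": list(design.conditions),
        "n_raters": len(design.raters),
        "repetitions": design.repetitions,
        "resolution": design.resolution,
        "n_scans": len(scans),
    }
    return panel, provenance


def random_rigid_transform(seed: _SeedLike, max_translation: float = 50.0) -> RigidTransform:
    """Uniform random rotation with a bounded uniform translation (seeded)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rng.uniform(-max_translation, max_translation, size=3)
    return RigidTransform(R, t)
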