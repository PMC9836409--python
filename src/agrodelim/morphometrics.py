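"""Wing-colour morphometrics: RGB disc profiles, NMDS ordination and PERMANOVA.

Inputs are per-disc RGB colour-picker measurements taken from standardized
photographs of dorsal wings (three discs per wing).  Discs are averaged into
one RGB profile per specimen, HSV is derived from the mean RGB, and group
structure (species/hybrid identity, soil substrate) is tested with a
permutational multivariate analysis of variance (PERMANOVA) on a Euclidean
distance matrix, visualised by non-metric multidimensional scaling (NMDS).
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from sklearn.manifold import MDS

__all__ = [
    "SpecimenColourProfile",
    "OrdinationResult",
    "PermanovaResult",
    "average_discs",
    "rgb_to_hsv",
    "hsv_to_rgb",
    "colour_distance_matrix",
    "nmds",
    "permanova",
    "ordination_plot",
]


@dataclass(frozen=True)
class SpecimenColourProfile:
    specimen_id: str
    r: float
    g: float
    b: float
    h: float
    s: float
    v: float
    group: str | None = None
    substrate: str | None = None

    def rgb(self) -> tuple[float, float, float]:
        return (self.r, self.g, self.b)

    def hsv(self) -> tuple[float, float, float]:
        return (self.h, self.s, self.v)


@dataclass(frozen=True)
class OrdinationResult:
    coordinates: pd.DataFrame  # index: specimen_id; columns: axis1, axis2, ...
    stress: float  # Kruskal stress-1
    n_starts: int
    seed: int


@dataclass(frozen=True)
class PermanovaResult:
    df: int
    pseudo_f: float
    p_value: float
    n_permutations: int
    seed: int
    ss_between: float
    ss_within: float


def rgb_to_hsv(r: float, g: float, b: float) -> tuple[float, float, float]:
    """Standard hexcone RGB->HSV; H in degrees [0, 360), S and V in [0, 1].

    Grey inputs (S = 0) return H = 0 by convention.
    """
    for name, c in zip("RGB", (r, g, b)):
        if not 0 <= c <= 255:
            raise ValueError(f"channel {name}={c} outside [0, 255]")
    h, s, v = colorsys.rgb_to_hsv(r / 255.0, g / 255.0, b / 255.0)
    return (h * 360.0) % 360.0, s, v


def hsv_to_rgb(h: float, s: float, v: float) -> tuple[float, float, float]:
    """Inverse hexcone conversion; returns RGB on the 0-255 scale."""
    r, g, b = colorsys.hsv_to_rgb((h % 360.0) / 360.0, s, v)
    return r * 255.0, g * 255.0, b * 255.0


def average_discs(
    measurements: pd.DataFrame,
    group_map: dict | None = None,
    substrate_map: dict | None = None,
) -> list[SpecimenColourProfile]:
    """Average per-disc RGB measurements into one profile per specimen.

    ``measurements`` needs columns specimen_id, disc, R, G, B.  HSV is derived
    from the per-specimen mean RGB.  Optional maps attach group/substrate
    labels.
    """
    required = {"specimen_id", "R", "G", "B"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if measurements[["R", "G", "B"]].isna().any().any():
        raise ValueError("missing channel values")
    profiles = []
    for sid, sub in measurements.groupby("specimen_id", sort=True):
        r, g, b = (float(sub[c].mean()) for c in ("R", "G", "B"))
        h, s, v = rgb_to_hsv(r, g, b)
        profiles.append(SpecimenColourProfile(
            specimen_id=str(sid), r=r, g=g, b=b, h=h, s=s, v=v,
            group=(group_map or {}).get(sid),
            substrate=(substrate_map or {}).get(sid),
        ))
    return profiles


def profile_table(profiles: list[SpecimenColourProfile]) -> pd.DataFrame:
    return pd.DataFrame([{
        "specimen_id": p.specimen_id, "R": p.r, "G": p.g, "B": p.b,
        "H": p.h, "S": p.s, "V": p.v, "group": p.group,
        "substrate": p.substrate,
    } for p in profiles])


def colour_distance_matrix(
    profiles: list[SpecimenColourProfile], space: str = "RGB"
) -> pd.DataFrame:
    """Euclidean distance matrix between specimen profiles in RGB or HSV."""
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    if space == "RGB":
        x = np.array([p.rgb() for p in profiles], dtype=float)
    elif space == "HSV":
        x = np.array([p.hsv() for p in profiles], dtype=float)
    else:
        raise ValueError(f"unknown colour space {space!r}")
    ids = [p.specimen_id for p in profiles]
    return pd.DataFrame(squareform(pdist(x)), index=ids, columns=ids)


def _classical_mds(dist: np.ndarray, dimensions: int) -> np.ndarray:
    """Torgerson double-centering start configuration."""
    n = dist.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dist ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:dimensions]
    vals = np.clip(vals[order], 0, None)
    return vecs[:, order] * np.sqrt(vals)


def nmds(
    dist: pd.DataFrame | np.ndarray,
    dimensions: int = 2,
    n_starts: int = 8,
    seed: int = 0,
    max_iter: int = 500,
) -> OrdinationResult:
    """Non-metric MDS by iterative stress minimization (monotone regression).

    Runs one fit initialised from a classical (Torgerson) MDS configuration
    plus ``n_starts - 1`` seeded random starts, and keeps the solution with
    the lowest Kruskal stress-1.  Coordinates are centred.
    """
    d = np.asarray(dist, dtype=float)
    ids = list(dist.index) if isinstance(dist, pd.DataFrame) else list(range(len(d)))
    if d.shape[0] < 3:
        raise ValueError("NMDS needs at least three points")
    if not np.any(d > 0):
        raise ValueError("degenerate all-zero distance matrix")

    def fit(init, random_state):
        model = MDS(
            n_components=dimensions, metric_mds=False, metric="precomputed",
            n_init=1, max_iter=max_iter, eps=1e-12, init="random",
            random_state=random_state, normalized_stress=True,
        )
        if init is not None:
            coords = model.fit_transform(d, init=init)
        else:
            coords = model.fit_transform(d)
        return model.stress_, coords

    best_stress, best_coords = fit(_classical_mds(d, dimensions), seed)
    rng = np.random.default_rng(seed)
    for _ in range(max(0, n_starts - 1)):
        sub = int(rng.integers(0, 2**31 - 1))
        stress, coords = fit(None, sub)
        if stress < best_stress:
            best_stress, best_coords = stress, coords

    best_coords = best_coords - best_coords.mean(axis=0)
    frame = pd.DataFrame(
        best_coords, index=ids,
        columns=[f"axis{k + 1}" for k in range(dimensions)],
    )
    return OrdinationResult(coordinates=frame, stress=float(best_stress),
                            n_starts=n_starts, seed=seed)


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, k: int, n: int,
              group_sizes: np.ndarray) -> tuple[float, float, float]:
    """Pseudo-F from squared distances and integer group codes."""
    ss_total = d2.sum() / (2 * n)  # sum over i<j of d^2 / N
    ss_within = 0.0
    for g in range(k):
        mask = codes == g
        ng = group_sizes[g]
        ss_within += d2[np.ix_(mask, mask)].sum() / (2 * ng)
    ss_between = ss_total - ss_within
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    return f, ss_between, ss_within


def permanova(
    dist: pd.DataFrame | np.ndarray,
    groups,
    n_permutations: int = 9999,
    seed: int = 0,
) -> PermanovaResult:
    """One-factor PERMANOVA: pseudo-F with a label-permutation null.

    SS_total = sum_{i<j} d_ij^2 / N; SS_within = sum over groups of the
    within-group pair sums divided by group size; pseudo-F =
    (SS_between/(k-1)) / (SS_within/(N-k)).  The p-value uses the add-one
    estimator (1 + #{F_perm >= F_obs}) / (n_permutations + 1).
    """
    d = np.asarray(dist, dtype=float)
    labels = np.asarray(list(groups))
    n = d.shape[0]
    if labels.shape[0] != n:
        raise ValueError("group labels do not match distance matrix")
    uniq, codes = np.unique(labels, return_inverse=True)
    k = len(uniq)
    if k < 2:
        raise ValueError("need at least two groups")
    sizes = np.bincount(codes, minlength=k)
    if (sizes == 0).any():
        raise ValueError("empty group")
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")

    d2 = d ** 2
    f_obs, ss_b, ss_w = _pseudo_f(d2, codes, k, n, sizes)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        f_perm, _, _ = _pseudo_f(d2, perm, k, n, sizes)
        if f_perm >= f_obs:
            hits += 1
    p = (1 + hits) / (n_permutations + 1)
    return PermanovaResult(df=k - 1, pseudo_f=float(f_obs), p_value=float(p),
                           n_permutations=n_permutations, seed=seed,
                           ss_between=float(ss_b), ss_within=float(ss_w))


def ordination_plot(
    ordination: OrdinationResult,
    groups: dict,
    path=None,
    confidence: float = 0.95,
):
    """NMDS scatter with per-group confidence ellipses (matplotlib Figure).

    Ellipses are Gaussian confidence regions from each group's 2-D covariance
    (drawn only for groups with at least three specimens).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse
    from scipy.stats import chi2

    coords = ordination.coordinates
    fig, ax = plt.subplots(figsize=(6, 5))
    scale = float(np.sqrt(chi2.ppf(confidence, df=2)))
    for grp in sorted({g for g in groups.values()}):
        ids = [i for i in coords.index if groups.get(i) == grp]
        pts = coords.loc[ids, ["axis1", "axis2"]].to_numpy()
        sc = ax.scatter(pts[:, 0], pts[:, 1], label=grp, s=30)
        if len(pts) >= 3:
            cov = np.cov(pts.T)
            vals, vecs = np.linalg.eigh(cov)
            angle = float(np.degrees(np.arctan2(vecs[1, -1], vecs[0, -1])))
            width, height = 2 * scale * np.sqrt(np.clip(vals[::-1], 0, None))
            ax.add_patch(Ellipse(pts.mean(axis=0), width, height, angle=angle,
                                 fill=False, color=sc.get_facecolor()[0]))
    ax.set_xlabel("NMDS axis 1")
    ax.set_ylabel("NMDS axis 2")
    ax.legend(fontsize=8)
    ax.set_title(f"NMDS (stress = {ordination.stress:.3f})")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
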