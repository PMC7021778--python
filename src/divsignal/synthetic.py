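"""Synthetic study generator with recorded ground truth.

Builds complete artificial studies mirroring the structure the pipeline
estimates: an ultrametric family phylogeny, family response parameters
evolving under Brownian motion (so downstream signal statistics have a known
expectation), a landscape of survey sites along an elevation gradient, and
per-family presence–absence matrices whose site richness follows each
family's elevational response and whose composition decays with distance.

Every stage draws from a named substream of one master seed, so a dataset is
fully reproducible from (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .data_model import OccurrenceMatrix, SiteMetadata
from .phylo import bm_covariance, read_newick, tip_labels, write_newick

__all__ = [
    "SyntheticTruth",
    "simulate_tree",
    "simulate_bm_traits",
    "simulate_landscape",
    "simulate_communities",
    "make_truth",
    "make_study",
    "write_dataset",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


@dataclass
class SyntheticTruth:
    """Ground-truth parameters of a simulated study.

    ``params`` has one row per family: peak (m), width (sd of member-species
    optima, m), amplitude (occupancy probability at the optimum), tolerance_z
    (per-species elevational tolerance, m; its inverse is the elevational
    turnover rate), turnover_xy (geographic decay rate, per coordinate unit).
    """

    newick: str
    params: pd.DataFrame
    peak_sigma2: float  # BM rate used to evolve peaks (m^2 / Ma)
    peak_root: float
    seed: int
    elev_range: tuple[float, float] = (0.0, 2300.0)
    extra: dict = field(default_factory=dict)

    @property
    def tree(self) -> dendropy.Tree:
        return read_newick(self.newick)

    def to_json(self, path: str) -> None:
        obj = dict(
            newick=self.newick,
            params=self.params.to_dict(orient="index"),
            peak_sigma2=self.peak_sigma2,
            peak_root=self.peak_root,
            seed=self.seed,
            elev_range=list(self.elev_range),
            extra=self.extra,
        )
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "SyntheticTruth":
        with open(path) as fh:
            obj = json.load(fh)
        params = pd.DataFrame.from_dict(obj["params"], orient="index")
        return cls(
            obj["newick"], params, obj["peak_sigma2"], obj["peak_root"],
            obj["seed"], tuple(obj["elev_range"]), obj.get("extra", {}),
        )


class _Lineage:
    __slots__ = ("t0", "t1", "children", "label")

    def __init__(self, t0: float):
        self.t0 = t0
        self.t1: float | None = None
        self.children: list["_Lineage"] = []
        self.label: str | None = None


def simulate_tree(n_tips: int, depth_ma: float = 300.0, seed=None) -> dendropy.Tree:
    """Pure-birth (Yule) topology rescaled to an exact ultrametric depth."""
    if n_tips < 2:
        raise ValueError("need >= 2 tips")
    rng = _rng(seed)
    root = _Lineage(0.0)
    active = [_Lineage(0.0), _Lineage(0.0)]
    root.children = list(active)
    root.t1 = 0.0
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        parent = active[i]
        parent.t1 = t
        kids = [_Lineage(t), _Lineage(t)]
        parent.children = kids
        active[i] = kids[0]
        active.append(kids[1])
    t_end = t + rng.exponential(1.0 / len(active))
    scale = depth_ma / t_end
    width = len(str(n_tips))
    for i, leaf in enumerate(active):
        leaf.t1 = t_end
        leaf.label = f"F{i + 1:0{width}d}"

    def nwk(node: _Lineage) -> str:
        bl = (node.t1 - node.t0) * scale
        if not node.children:
            return f"{node.label}:{bl:.8f}"
        inner = ",".join(nwk(c) for c in node.children)
        return f"({inner}):{bl:.8f}"

    return read_newick("(" + ",".join(nwk(c) for c in root.children) + ");")


def simulate_bm_traits(
    tree: dendropy.Tree,
    sigma2: float,
    root_value: float = 0.0,
    n_reps: int = 1,
    seed=None,
) -> pd.DataFrame:
    """Brownian-motion tip values: each row drawn MVN(root·1, σ²C)."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    rng = _rng(seed)
    labels = tip_labels(tree)
    C = bm_covariance(tree, labels).to_numpy()
    n = len(labels)
    if sigma2 == 0:
        X = np.full((n_reps, n), root_value)
    else:
        L = np.linalg.cholesky(C + 1e-12 * np.trace(C) / n * np.eye(n))
        X = root_value + np.sqrt(sigma2) * rng.standard_normal((n_reps, n)) @ L.T
    return pd.DataFrame(X, columns=labels)


def simulate_landscape(
    n_sites: int = 300,
    elev_range: tuple[float, float] = (0.0, 2300.0),
    n_habitats: int = 4,
    seed=None,
    extent: float = 100.0,
    habitat_drift: float = 2.0,
) -> SiteMetadata:
    """Survey sites on a square landscape crossed by an elevation gradient.

    Coordinates are uniform on [0, extent]²; elevations uniform over
    ``elev_range``.  Habitat cover proportions come from a softmax of
    habitat-specific logits that drift linearly with elevation, so habitat
    dissimilarity correlates with elevational distance when
    ``habitat_drift`` > 0 (and is independent at 0).
    """
    if n_sites < 20:
        raise ValueError("need >= 20 sites")
    rng = _rng(seed)
    x = rng.uniform(0, extent, n_sites)
    y = rng.uniform(0, extent, n_sites)
    elev = rng.uniform(elev_range[0], elev_range[1], n_sites)
    u = (elev - elev_range[0]) / (elev_range[1] - elev_range[0]) - 0.5
    grad = np.linspace(-1, 1, n_habitats) * habitat_drift
    logits = grad[None, :] * u[:, None] + rng.normal(0, 0.3, (n_sites, n_habitats))
    covers = np.exp(logits)
    covers /= covers.sum(axis=1, keepdims=True)
    ids = [f"S{i + 1:04d}" for i in range(n_sites)]
    tab = pd.DataFrame({"x": x, "y": y, "elevation": elev}, index=ids)
    for h in range(n_habitats):
        tab[f"habitat_{h + 1}"] = covers[:, h]
    tab.index.name = "site"
    return SiteMetadata(tab)


def make_truth(
    tree: dendropy.Tree,
    seed=None,
    peak_root: float = 1200.0,
    peak_sd: float = 400.0,
    width: float = 250.0,
    amplitude: float = 0.9,
    tolerance_z=None,
    turnover_xy=None,
    elev_range: tuple[float, float] = (0.0, 2300.0),
) -> SyntheticTruth:
    """Ground-truth family parameters; peaks evolve under Brownian motion.

    ``peak_sd`` is the marginal BM standard deviation of Peak-α at the tips
    (σ² = peak_sd²/depth).  Peaks are clipped to stay inside the elevation
    range.  Tolerances and geographic turnover rates default to lognormal
    draws around 300 m and 0.03 per coordinate unit.
    """
    rng = _rng(seed)
    labels = tip_labels(tree)
    n = len(labels)
    depth = float(np.max(np.diag(bm_covariance(tree, labels).to_numpy())))
    sigma2 = peak_sd**2 / depth
    peaks = simulate_bm_traits(tree, sigma2, peak_root, 1, rng).iloc[0]
    margin = 0.05 * (elev_range[1] - elev_range[0])
    peaks = peaks.clip(elev_range[0] + margin, elev_range[1] - margin)
    if tolerance_z is None:
        tolerance_z = np.exp(rng.normal(np.log(300.0), 0.4, n))
    if turnover_xy is None:
        turnover_xy = np.exp(rng.normal(np.log(0.03), 0.3, n))
    params = pd.DataFrame(
        {
            "peak": peaks.to_numpy(),
            "width": np.full(n, float(width)),
            "amplitude": np.full(n, float(amplitude)),
            "tolerance_z": np.asarray(tolerance_z, dtype=float),
            "turnover_xy": np.asarray(turnover_xy, dtype=float),
        },
        index=labels,
    )
    return SyntheticTruth(
        write_newick(tree).strip(), params, sigma2, peak_root,
        int(seed) if isinstance(seed, (int, np.integer)) else -1, elev_range,
    )


def simulate_communities(
    tree: dendropy.Tree,
    truth: SyntheticTruth,
    meta: SiteMetadata,
    species_per_family: int = 12,
    seed=None,
) -> OccurrenceMatrix:
    """Presence–absence matrix realizing the truth parameters.

    Each member species gets an elevational optimum drawn around the
    family's peak (sd = width) and a geographic range center; its occupancy
    probability at a site is amplitude × Gaussian(elevation; optimum,
    tolerance_z) × exp(−turnover_xy × geographic distance to the center),
    realized as independent Bernoulli draws.  A family with no realized
    occurrence is redrawn once, then reported as an error.
    """
    rng = _rng(seed)
    labels = tip_labels(tree)
    missing = [l for l in labels if l not in truth.params.index]
    if missing:
        raise ValueError(f"truth lacks parameters for {missing}")
    t = meta.table
    elev = t["elevation"].to_numpy(float)
    xy = t[["x", "y"]].to_numpy(float)
    lo = xy.min(axis=0)
    hi = xy.max(axis=0)
    cols = {}
    taxonomy = {}
    for fam in labels:
        p = truth.params.loc[fam]
        for attempt in range(2):
            block = {}
            for s in range(species_per_family):
                opt = rng.normal(p["peak"], p["width"])
                center = rng.uniform(lo, hi)
                d = np.hypot(xy[:, 0] - center[0], xy[:, 1] - center[1])
                prob = (
                    p["amplitude"]
                    * np.exp(-0.5 * ((elev - opt) / p["tolerance_z"]) ** 2)
                    * np.exp(-p["turnover_xy"] * d)
                )
                block[f"{fam}_sp{s + 1:02d}"] = (rng.random(len(elev)) < prob).astype(int)
            if any(v.sum() for v in block.values()):
                break
        else:
            raise ValueError(f"family {fam!r} realized no occurrences after retry")
        for k, v in block.items():
            cols[k] = v
            taxonomy[k] = fam
    inc = pd.DataFrame(cols, index=t.index)
    return OccurrenceMatrix(inc, pd.Series(taxonomy, name="family"))


def make_study(
    n_families: int = 12,
    n_sites: int = 300,
    species_per_family: int = 12,
    depth_ma: float = 300.0,
    seed: int = 0,
    **truth_kwargs,
):
    """One full synthetic study: (tree, truth, metadata, occurrence matrix)."""
    r_tree, r_truth, r_land, r_comm = _substreams(seed, 4)
    tree = simulate_tree(n_families, depth_ma, r_tree)
    truth = make_truth(tree, r_truth, **truth_kwargs)
    truth.seed = seed
    meta = simulate_landscape(n_sites, truth.elev_range, seed=r_land)
    occ = simulate_communities(tree, truth, meta, species_per_family, r_comm)
    return tree, truth, meta, occ


def write_dataset(outdir: str, tree, truth, meta, occ) -> dict:
    """Write the CSV dialects ``data_model.read_occurrence`` reads, plus the
    tree (Newick) and truth (JSON).  Returns the path map."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "matrix": os.path.join(outdir, "occurrence.csv"),
        "taxonomy": os.path.join(outdir, "taxonomy.csv"),
        "metadata": os.path.join(outdir, "sites.csv"),
        "tree": os.path.join(outdir, "tree.nwk"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    occ.incidence.rename_axis("site").to_csv(paths["matrix"])
    pd.DataFrame(
        {"species": occ.taxonomy.index, "family": occ.taxonomy.values}
    ).to_csv(paths["taxonomy"], index=False)
    meta.table.rename_axis("site").to_csv(paths["metadata"])
    write_newick(tree, paths["tree"])
    truth.to_json(paths["truth"])
    return paths
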