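"""Synthetic inputs with known ground truth for both analysis stages.

Two families of generators:

* **Characters on trees** — random rooted binary topologies with unit branch
  lengths, and forward Mk simulation of multistate characters at a known
  rate, for exercising likelihoods, rate estimation and reconstruction.

* **Section images** — controlled planar point processes (uniform "poisson",
  centred square "grid", Thomas-type "cluster") rendered into paired
  confocal-like channels: Gaussian blobs for proliferating cells on a noisy
  background, and a filled elliptical tissue silhouette with a denser
  nucleus blob field for the counterstain. Ground-truth cell centres and
  tissue width are returned for oracle tests.

``make_paper_like_dataset`` emits the full nested study design (3 species-like
series x 2 positions x 3 individuals x 3 sections = 54 paired images) with
joint/phalanx entropy ratios planted at ~5x, ~2x and ~1 via calibrated
proliferating-cell counts (see ``calibration.json``).

All generators are pure functions of (parameters, seed): the RNG is a local
``numpy.random.Generator``, never global state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .characters import CharacterStateMap
from .errors import InputError, RenderError, ValidationError
from .mk import MkModel, transition_matrix
from .tree import PhyloTree

__all__ = [
    "generate_random_tree",
    "simulate_mk_characters",
    "SimulatedCharacterDataset",
    "PointPattern",
    "generate_point_pattern",
    "RenderSpec",
    "render_section",
    "make_paper_like_dataset",
    "paper_like_measurements",
    "load_calibration",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# trees and characters


def generate_random_tree(n_tips: int, seed) -> PhyloTree:
    """Random rooted binary tree by sequential pairing, all branch lengths 1.

    Starting from ``n_tips`` lineages (labelled t1..tn), two lineages chosen
    uniformly at random are joined under a new parent until one remains
    (a coalescent-style topology). Deterministic given the seed.
    """
    if n_tips < 2:
        raise ValidationError(f"need >= 2 tips, got {n_tips}")
    rng = _rng(seed)
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=int)
    labels = [f"t{i + 1}" for i in range(n_tips)] + [None] * (n_tips - 1)
    active = list(range(n_tips))
    nxt = n_tips
    while len(active) > 1:
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[int(i)], active[int(j)]
        parent[a] = parent[b] = nxt
        active = [v for v in active if v not in (a, b)] + [nxt]
        nxt += 1
    return PhyloTree(parent, np.ones(n_nodes), labels, root=n_nodes - 1)


@dataclass
class SimulatedCharacterDataset:
    """Forward-simulated Mk characters with the generating tree and model."""

    tree: PhyloTree
    model: MkModel
    characters: list
    seed: int
    node_states: np.ndarray = field(default=None, repr=False)  # (n_nodes, n_chars)


def simulate_mk_characters(tree: PhyloTree, model: MkModel, n_chars: int, seed) -> SimulatedCharacterDataset:
    """Simulate characters down the tree: uniform root state, then each edge
    transitions the state with the closed-form Mk probabilities."""
    if n_chars < 1:
        raise ValidationError(f"n_chars must be >= 1, got {n_chars}")
    rng = _rng(seed)
    k = model.k
    states = np.empty((tree.n_nodes, n_chars), dtype=np.int64)
    states[tree.root] = rng.integers(0, k, size=n_chars)
    for v in tree.preorder:
        if v == tree.root:
            continue
        P = transition_matrix(model, float(tree.branch_lengths[v]))
        cum = P.cumsum(axis=1)
        u = rng.random(n_chars)
        states[v] = (u[:, None] > cum[states[tree.parent[v]]]).sum(axis=1)
    chars = [
        CharacterStateMap({tree.labels[t]: int(states[t, j]) for t in tree.tips}, k)
        for j in range(n_chars)
    ]
    return SimulatedCharacterDataset(
        tree=tree,
        model=model,
        characters=chars,
        seed=seed if isinstance(seed, int) else -1,
        node_states=states,
    )


# ---------------------------------------------------------------------------
# point patterns


@dataclass
class PointPattern:
    """Continuous points in a width x height region, with provenance."""

    points: np.ndarray  # (n, 2) columns (x, y)
    width: float
    height: float
    kind: str
    params: dict
    seed: int | None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64)
        x, y = self.points[:, 0], self.points[:, 1]
        if (x < 0).any() or (x > self.width).any() or (y < 0).any() or (y > self.height).any():
            raise ValidationError("points fall outside the region")

    @property
    def n(self) -> int:
        return self.points.shape[0]


def generate_point_pattern(kind: str, n: int, region, params=None, seed=None) -> PointPattern:
    """Generate a planar point pattern of a requested disorder class.

    kinds: ``poisson`` (uniform i.i.d.), ``grid`` (centred square lattice
    using the largest perfect square <= n points), ``cluster`` (Thomas-type:
    ``n_parents`` uniform parents, Gaussian offspring with sd
    ``radius``, resampled until inside the region).
    """
    if n < 2:
        raise ValidationError(f"need n >= 2 points, got {n}")
    w, h = float(region[0]), float(region[1])
    if w <= 0 or h <= 0:
        raise ValidationError(f"region must be positive, got {region}")
    params = dict(params or {})
    rng = _rng(seed)
    if kind == "poisson":
        pts = rng.uniform([0, 0], [w, h], size=(n, 2))
    elif kind == "grid":
        side = int(np.floor(np.sqrt(n)))
        xs = (np.arange(side) + 0.5) * (w / side)
        ys = (np.arange(side) + 0.5) * (h / side)
        gx, gy = np.meshgrid(xs, ys)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        params["n_used"] = side * side
    elif kind == "cluster":
        n_parents = int(params.get("n_parents", 5))
        radius = float(params.get("radius", min(w, h) / 20.0))
        if n_parents < 1:
            raise ValidationError("cluster needs n_parents >= 1")
        parents = rng.uniform([0, 0], [w, h], size=(n_parents, 2))
        assign = rng.integers(0, n_parents, size=n)
        pts = parents[assign] + rng.normal(0.0, radius, size=(n, 2))
        bad = ~(
            (pts[:, 0] >= 0) & (pts[:, 0] <= w) & (pts[:, 1] >= 0) & (pts[:, 1] <= h)
        )
        while bad.any():
            m = int(bad.sum())
            pts[bad] = parents[assign[bad]] + rng.normal(0.0, radius, size=(m, 2))
            bad = ~(
                (pts[:, 0] >= 0) & (pts[:, 0] <= w) & (pts[:, 1] >= 0) & (pts[:, 1] <= h)
            )
        params.update(n_parents=n_parents, radius=radius)
    else:
        raise InputError(f"unknown point-pattern kind {kind!r}")
    return PointPattern(
        points=pts,
        width=w,
        height=h,
        kind=kind,
        params=params,
        seed=seed if isinstance(seed, int) else None,
    )


# ---------------------------------------------------------------------------
# rendering


@dataclass
class RenderSpec:
    """How to rasterise a point pattern into confocal-like channel images.

    ``shape`` is (rows, cols) in pixels (>= 32 each); ``sigma`` the Gaussian
    point-spread of a proliferating-cell blob in pixels; intensities are on
    the 8-bit scale.
    """

    shape: tuple = (512, 512)
    sigma: float = 2.0
    peak: float = 220.0
    background: float = 10.0
    noise_sd: float = 5.0
    silhouette: float = 110.0
    nuclei_peak: float = 200.0
    nuclei_sigma: float = 1.5
    n_nuclei: int | None = None
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.shape, int):
            self.shape = (self.shape, self.shape)
        if min(self.shape) < 32:
            raise ValidationError(f"image size must be >= 32 px, got {self.shape}")
        if self.sigma <= 0:
            raise ValidationError("sigma must be > 0")
        for v in (self.peak, self.background, self.nuclei_peak, self.silhouette):
            if not 0 <= v <= 255:
                raise ValidationError("intensities must lie in [0, 255]")


def _add_blobs(img: np.ndarray, centres_rc: np.ndarray, sigma: float, peak: float) -> None:
    """Accumulate Gaussian blobs (in place); centres are (row, col) floats."""
    H, W = img.shape
    r = int(np.ceil(4 * sigma))
    for cy, cx in centres_rc:
        y0, y1 = int(np.floor(cy)) - r, int(np.floor(cy)) + r + 1
        x0, x1 = int(np.floor(cx)) - r, int(np.floor(cx)) + r + 1
        yy = np.arange(max(y0, 0), min(y1, H))
        xx = np.arange(max(x0, 0), min(x1, W))
        if yy.size == 0 or xx.size == 0:
            continue
        g = np.exp(-((yy[:, None] - cy) ** 2 + (xx[None, :] - cx) ** 2) / (2 * sigma**2))
        img[yy[0] : yy[-1] + 1, xx[0] : xx[-1] + 1] += peak * g


def render_section(pattern: PointPattern, spec: RenderSpec):
    """Render one section as (nuclei image, proliferating image, ground truth).

    The pattern's region is centred in the image. The nuclei channel holds a
    filled ellipse covering the region (semi-axes region/2 * sqrt(2), so the
    rectangle is inscribed) plus a denser field of nucleus blobs and noise;
    the proliferating channel holds one blob per pattern point plus noise.
    Ground truth: planted blob centres in (row, col) pixel coordinates, the
    continuous tissue width (ellipse major row extent), and the pattern.
    """
    H, W = spec.shape
    w, h = pattern.width, pattern.height
    a = (w / 2.0) * np.sqrt(2.0)  # ellipse semi-axis along rows (width)
    b = (h / 2.0) * np.sqrt(2.0)
    if 2 * a > W or 2 * b > H:
        raise RenderError(
            f"ellipse covering the {w:g}x{h:g} region does not fit a {H}x{W} image"
        )
    ox, oy = (W - w) / 2.0, (H - h) / 2.0
    pad = 4 * spec.sigma
    px = pattern.points[:, 0] + ox
    py = pattern.points[:, 1] + oy
    if (px < pad).any() or (px > W - pad).any() or (py < pad).any() or (py > H - pad).any():
        raise RenderError("blobs fall within one blob radius of the image border")
    centres = np.column_stack([py, px])  # (row, col)

    rng = _rng(spec.seed)
    prolif = rng.normal(spec.background, spec.noise_sd, size=(H, W))
    _add_blobs(prolif, centres, spec.sigma, spec.peak)

    nuclei = rng.normal(spec.background, spec.noise_sd, size=(H, W))
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    yy, xx = np.ogrid[:H, :W]
    inside = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    nuclei[inside] += spec.silhouette
    n_nuclei = spec.n_nuclei if spec.n_nuclei is not None else min(max(4 * pattern.n, 150), 2000)
    nuc_pts = rng.uniform([0, 0], [w, h], size=(n_nuclei, 2))
    nuc_centres = np.column_stack([nuc_pts[:, 1] + oy, nuc_pts[:, 0] + ox])
    _add_blobs(nuclei, nuc_centres, spec.nuclei_sigma, spec.nuclei_peak)

    to_u8 = lambda x: np.clip(np.round(x), 0, 255).astype(np.uint8)
    truth = {
        "centres": centres,
        "tissue_width": 2.0 * a,
        "n": pattern.n,
        "pattern": pattern,
    }
    return to_u8(nuclei), to_u8(prolif), truth


# ---------------------------------------------------------------------------
# the nested study-design dataset


def load_calibration() -> dict:
    """Per-series cell counts and geometry planted by the pilot calibration."""
    with resources.files("webfoot").joinpath("calibration.json").open() as fh:
        return json.load(fh)


def _iter_paper_like(seed: int, calib: dict):
    region = (calib["region"]["width"], calib["region"]["height"])
    shape = tuple(calib["image"])
    render_kw = dict(calib.get("render", {}))
    series = calib["series"]
    for si, species in enumerate(sorted(series)):
        for ind in (1, 2, 3):
            for pi, position in enumerate(("joint", "phalanx")):
                n_cells = int(series[species][position])
                for sec in (1, 2, 3):
                    ss = np.random.SeedSequence([int(seed), si, ind, pi, sec])
                    pat_rng, render_seed = ss.spawn(2)
                    pattern = generate_point_pattern(
                        "poisson", n_cells, region, seed=np.random.default_rng(pat_rng)
                    )
                    spec = RenderSpec(
                        shape=shape, seed=np.random.default_rng(render_seed), **render_kw
                    )
                    nuc, pro, truth = render_section(pattern, spec)
                    meta = {
                        "species": species,
                        "individual": f"ind{ind}",
                        "position": position,
                        "section": sec,
                        "n_cells": n_cells,
                        "region_width": region[0],
                        "region_height": region[1],
                    }
                    yield meta, nuc, pro, truth


def make_paper_like_dataset(seed: int, out_dir=None) -> pd.DataFrame:
    """Render the full nested design: 3 series x 2 positions x 3 individuals
    x 3 sections = 54 paired images.

    With ``out_dir`` the images are written as
    ``species/individual/position/section_{i}_{nuclei|prolif}.png`` plus a
    ``manifest.tsv`` (one row per section, including the planted calibration
    constants); the manifest DataFrame is returned either way.
    """
    calib = load_calibration()
    rows = []
    for meta, nuc, pro, _truth in _iter_paper_like(seed, calib):
        row = dict(meta)
        if out_dir is not None:
            d = Path(out_dir) / meta["species"] / meta["individual"] / meta["position"]
            d.mkdir(parents=True, exist_ok=True)
            npath = d / f"section_{meta['section']}_nuclei.png"
            ppath = d / f"section_{meta['section']}_prolif.png"
            Image.fromarray(nuc).save(npath)
            Image.fromarray(pro).save(ppath)
            row["nuclei_path"] = str(npath)
            row["prolif_path"] = str(ppath)
        rows.append(row)
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(Path(out_dir) / "manifest.tsv", sep="\t", index=False)
    return manifest


def paper_like_measurements(seed: int):
    """Generate the paper-like dataset in memory and push every section
    through the measurement pipeline; returns the list of
    :class:`~webfoot.entropy.SectionMeasurement`."""
    from .entropy import measure_section

    calib = load_calibration()
    out = []
    for meta, nuc, pro, _truth in _iter_paper_like(seed, calib):
        out.append(
            measure_section(
                nuc,
                pro,
                species=meta["species"],
                individual=meta["individual"],
                position=meta["position"],
                section=meta["section"],
            )
        )
    return out
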