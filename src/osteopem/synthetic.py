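"""Synthetic fixtures: Yule trees, phylogenetic traits, labelled section masks.

Every stage of the pipeline can be exercised without downloads.  The trait
generator reproduces the statistical structure the analysis assumes: the
log10 response is a linear function of log10 primary osteon density plus a
Brownian-motion deviation accumulated along the tree plus independent
Gaussian noise,

    log10(response) = beta0 + beta1 * log10(density) + BM(sigma2_bm) + N(0, sigma_e^2).

Defaults are the recovery-test conditions used throughout the test suite
(beta1 = 1, sigma2_bm = 0.5 per Ma, sigma_e = 0.1); the Yule birth rate
(1.0 per Ma) and density range (0.02-0.40) are chosen so that simulated
trees a few Ma deep carry log-trait spreads of order one, comparable to
real amniote histology datasets.  "Fossil" targets are made by withholding
the response of known tips, so every prediction has an exact recorded truth.

All generators are driven by a single seeded NumPy generator; a fixed seed
gives byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import histology
from .histology import SectionMask
from .model import ROLE_TARGET, ROLE_TRAINING, TraitTable
from .trees import Node, PhyloTree


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the standard test conditions."""

    n_tips: int = 32
    birth_rate: float = 1.0  # Yule speciation rate, per Ma
    sigma2_bm: float = 0.5  # BM variance of the log10 response, per Ma
    beta0: float = 0.0  # intercept of the log-log trait relation
    beta1: float = 1.0  # slope on log10 density
    sigma_e: float = 0.1  # s.d. of independent log10 noise
    density_range: tuple[float, float] = (0.02, 0.40)
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 4:
            raise ValueError("n_tips must be >= 4")
        for name in ("birth_rate",):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("sigma2_bm", "sigma_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.density_range
        if not (0 < lo < hi < 1):
            raise ValueError("density_range must satisfy 0 < lo < hi < 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def simulate_tree(
    n_tips: int, birth_rate: float = 1.0, rng: np.random.Generator | None = None
) -> PhyloTree:
    """Pure-birth (Yule) ultrametric tree with ``n_tips`` tips, lengths in Ma.

    Starting from the root's two daughter lineages, each of k extant
    lineages waits Exp(k * birth_rate) before one (uniformly chosen) splits;
    after the last split the process runs one further waiting time so tip
    edges have positive length.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = rng if rng is not None else np.random.default_rng()
    root = Node()
    active = [root.add_child(Node(length=0.0)), root.add_child(Node(length=0.0))]
    k = 2
    while True:
        wait = rng.exponential(1.0 / (birth_rate * k))
        for node in active:
            node.length += wait
        if k == n_tips:
            break
        idx = rng.integers(k)
        parent = active[idx]
        children = [parent.add_child(Node(length=0.0)) for _ in range(2)]
        active[idx : idx + 1] = children
        k += 1
    for i, node in enumerate(active):
        node.label = f"t{i + 1}"
    return PhyloTree(root)


def simulate_bm(
    tree: PhyloTree, sigma2: float, rng: np.random.Generator
) -> dict[str, float]:
    """One Brownian-motion realisation along the tree; returns tip deviations."""
    values: dict[int, float] = {id(tree.root): 0.0}
    for node in tree.preorder():
        if node.parent is None:
            continue
        step = rng.normal(0.0, np.sqrt(sigma2 * node.length)) if sigma2 > 0 else 0.0
        values[id(node)] = values[id(node.parent)] + step
    return {t.label: values[id(t)] for t in tree.tips()}


def simulate_traits(
    tree: PhyloTree,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    target_labels: list[str] | None = None,
) -> tuple[TraitTable, dict]:
    """Draw densities and responses for every tip; returns (table, truth record).

    log10 density is uniform over the configured range; the log10 response
    follows the generating equation in the module docstring.  Tips named in
    ``target_labels`` have their response withheld (role ``target``); the
    truth record keeps every latent value, including the withheld responses.
    """
    rng = rng if rng is not None else config.rng()
    target_labels = list(target_labels or [])
    labels = tree.tip_labels()
    unknown = sorted(set(target_labels) - set(labels))
    if unknown:
        raise ValueError(f"target labels not in tree: {unknown}")
    lo, hi = config.density_range
    log_density = rng.uniform(np.log10(lo), np.log10(hi), size=len(labels))
    bm = simulate_bm(tree, config.sigma2_bm, rng)
    noise = (
        rng.normal(0.0, config.sigma_e, size=len(labels))
        if config.sigma_e > 0
        else np.zeros(len(labels))
    )
    log_response = np.array(
        [
            config.beta0 + config.beta1 * ld + bm[lab] + eps
            for lab, ld, eps in zip(labels, log_density, noise)
        ]
    )
    rows = []
    for i, lab in enumerate(labels):
        is_target = lab in target_labels
        rows.append(
            {
                "species": lab,
                "density": 10.0 ** log_density[i],
                "response": np.nan if is_target else 10.0 ** log_response[i],
                "role": ROLE_TARGET if is_target else ROLE_TRAINING,
            }
        )
    table = TraitTable(pd.DataFrame(rows))
    truth = {
        "seed": config.seed,
        "config": asdict(config),
        "log_density": {lab: float(v) for lab, v in zip(labels, log_density)},
        "bm_deviation": {lab: float(bm[lab]) for lab in labels},
        "noise": {lab: float(v) for lab, v in zip(labels, noise)},
        "log_response": {lab: float(v) for lab, v in zip(labels, log_response)},
    }
    return table, truth


def simulate_dataset(
    config: SimulationConfig, n_targets: int = 1
) -> tuple[PhyloTree, TraitTable, dict]:
    """Tree + trait table with ``n_targets`` randomly chosen fossil-like targets."""
    rng = config.rng()
    tree = simulate_tree(config.n_tips, config.birth_rate, rng)
    labels = tree.tip_labels()
    if n_targets >= len(labels) - 3:
        raise ValueError("too many targets for the number of tips")
    chosen = sorted(rng.choice(len(labels), size=n_targets, replace=False))
    targets = [labels[i] for i in chosen]
    table, truth = simulate_traits(tree, config, rng, target_labels=targets)
    truth["targets"] = targets
    return tree, table, truth


def simulate_section_mask(
    target_density: float,
    radius_range: tuple[int, int] = (4, 9),
    size: int = 512,
    seed: int = 0,
    margin: int = 24,
    max_attempts: int = 200_000,
) -> tuple[SectionMask, float]:
    """Bone field with non-overlapping rasterised osteon discs at a known fraction.

    A circular bone region (label 1) surrounded by a background ring (label
    0) is seeded with discs (label 2) of uniformly drawn radius at uniform
    positions, rejecting overlaps and bone-boundary crossings, until the
    osteon pixel fraction first reaches ``target_density``.  Returns the
    mask and the achieved fraction (slightly above target by at most one
    disc's contribution).
    """
    from skimage.draw import disk

    if not (0.0 <= target_density < 0.6):
        raise ValueError("target density must lie in [0, 0.6)")
    rng = np.random.default_rng(seed)
    labels = np.zeros((size, size), dtype=np.uint8)
    centre = (size - 1) / 2.0
    bone_radius = size / 2.0 - margin
    rr, cc = disk((centre, centre), bone_radius, shape=labels.shape)
    labels[rr, cc] = histology.BONE
    n_bone_total = len(rr)

    # rasterised discs must not share pixels with each other or leave the
    # bone field; when the field jams, the sampled radius range shrinks so
    # smaller discs can fill the interstices
    n_osteon = 0
    attempts = 0
    rejections = 0
    rmin, rmax = radius_range
    rmax_cur = float(rmax)
    while n_osteon / n_bone_total < target_density:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not reach density {target_density} with radii {radius_range} "
                f"after {max_attempts} attempts"
            )
        attempts += 1
        r = rng.uniform(rmin, rmax_cur)
        cr = rng.uniform(margin, size - margin)
        ccn = rng.uniform(margin, size - margin)
        if np.hypot(cr - centre, ccn - centre) + r >= bone_radius:
            rejections += 1
            continue
        dr, dc = disk((cr, ccn), r, shape=labels.shape)
        if np.any(labels[dr, dc] != histology.BONE):
            rejections += 1
            if rejections % 500 == 0 and rmax_cur > rmin:
                rmax_cur = max(float(rmin), 0.8 * rmax_cur)
            continue
        labels[dr, dc] = histology.OSTEON
        n_osteon += len(dr)
    achieved = n_osteon / n_bone_total
    return SectionMask(labels), achieved


def write_dataset(
    outdir, config: SimulationConfig, n_targets: int = 1
) -> dict[str, Path]:
    """Write tree.nwk, traits.csv and truth.json for one synthetic study."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree, table, truth = simulate_dataset(config, n_targets=n_targets)
    paths = {
        "tree": outdir / "tree.nwk",
        "traits": outdir / "traits.csv",
        "truth": outdir / "truth.json",
    }
    tree.write(paths["tree"], precision=None)
    table.to_csv(paths["traits"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
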