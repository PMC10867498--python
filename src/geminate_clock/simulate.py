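"""Simulation of geminate-pair multi-locus datasets at known rates.

The generator emulates the structure of a trans-Isthmian geminate pair:
two clades whose ancestors split ``t_split`` Myr ago, with neutral
coalescent genealogies inside each clade (optionally nested into
regional subclades that split at a fixed fraction of the clade age) and
sequences evolved along the genealogy under TN93, one locus at a time.
Genealogies are ultrametric in time and every lineage evolves at the
locus substitution rate (half the divergence rate), i.e. a strict
clock; `simulate_clock_violation` breaks the clock by scaling one
sample's pendant branch.

All randomness flows from one seeded generator, so identical
configurations and seeds yield bit-identical alignments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tn93 import BASES, TN93Model, TN93Params
from .alignment import Alignment, GroupPartition, SequenceRecord
from .errors import ConfigError

__all__ = [
    "LocusConfig",
    "SimulationConfig",
    "simulate_geminate",
    "simulate_clock_violation",
    "default_config",
]


@dataclass(frozen=True)
class LocusConfig:
    """One locus: length, divergence rate and substitution parameters."""

    name: str
    length: int
    divergence_rate: float  # proportion per Myr, both lineages combined
    tn93: TN93Params = TN93Params((0.25, 0.25, 0.25, 0.25), 4.0, 4.0)
    gamma_shape: float | None = None  # None => homogeneous site rates

    def __post_init__(self):
        if self.length <= 0:
            raise ConfigError(f"{self.name}: length must be positive")
        if self.divergence_rate < 0:
            raise ConfigError(f"{self.name}: negative divergence rate")

    @property
    def substitution_rate(self) -> float:
        """Per-lineage rate: half the divergence rate."""
        return self.divergence_rate / 2.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study design for a synthetic geminate dataset."""

    t_split: float = 2.8  # Myr; Isthmus of Panama closure
    loci: tuple[LocusConfig, ...] = ()
    n_per_clade: int = 12
    intra_clade_theta: float = 0.005  # expected within-clade diversity at locus 1
    n_regions_per_clade: int = 1
    region_split_fraction: float = 0.4  # regions split at this fraction of t_split
    group_labels: tuple[str, str] = ("western_Atlantic", "eastern_Pacific")
    seed: int = 0

    def __post_init__(self):
        if self.t_split <= 0:
            raise ConfigError("t_split must be positive")
        if self.n_per_clade < 1:
            raise ConfigError("n_per_clade must be >= 1")
        if self.intra_clade_theta < 0:
            raise ConfigError("intra_clade_theta must be >= 0")
        if self.n_regions_per_clade < 1 or self.n_regions_per_clade > self.n_per_clade:
            raise ConfigError("n_regions_per_clade must be in 1..n_per_clade")
        if not (0 < self.region_split_fraction < 1):
            raise ConfigError("region_split_fraction must be in (0, 1)")
        if not self.loci:
            raise ConfigError("at least one locus required")
        object.__setattr__(self, "loci", tuple(self.loci))


def default_config(seed: int = 0) -> SimulationConfig:
    """Study-like defaults: three loci at the calibrated rates.

    COI-like and 16S-like mitochondrial loci (AT-rich, strong
    transition bias) and a slow ANT-like nuclear locus, at the
    divergence rates derived from the 2.8-Myr Isthmus calibration.
    """
    mito_pi = (0.28, 0.18, 0.18, 0.36)
    nuc_pi = (0.27, 0.23, 0.23, 0.27)
    return SimulationConfig(
        t_split=2.8,
        loci=(
            LocusConfig("COI", 658, 0.049, TN93Params(mito_pi, 6.0, 6.0)),
            LocusConfig("16S", 459, 0.020, TN93Params(mito_pi, 6.0, 6.0)),
            LocusConfig("ANT", 553, 0.002, TN93Params(nuc_pi, 3.0, 3.0)),
        ),
        n_per_clade=12,
        intra_clade_theta=0.005,
        seed=seed,
    )


class _SimNode:
    __slots__ = ("time", "children", "label", "pendant_scale")

    def __init__(self, time: float, children=None, label: str | None = None):
        self.time = time  # Myr before present
        self.children = children or []
        self.label = label
        self.pendant_scale = 1.0


def _kingman(rng, tips: list[_SimNode], scale: float, start_time: float) -> _SimNode:
    """Coalesce ``tips`` (all at time <= start_time) under Kingman(scale)."""
    lineages = list(tips)
    t = start_time
    if scale == 0.0:
        node = _SimNode(t, list(lineages))
        return node if len(lineages) > 1 else lineages[0]
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(scale / (k * (k - 1) / 2.0))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        b = lineages.pop(j)
        a = lineages.pop(i)
        lineages.append(_SimNode(t, [a, b]))
    return lineages[0]


def _rescale_below(node: _SimNode, cap: float) -> None:
    """Compress node times so the subtree MRCA sits below ``cap``."""
    times = []

    def collect(n):
        times.append(n.time)
        for c in n.children:
            collect(c)

    collect(node)
    top = max(times)
    if top <= cap or top == 0:
        return

    def scale(n):
        n.time = n.time * cap / top
        for c in n.children:
            scale(c)

    scale(node)


def _clade_genealogy(rng, labels: list[str], cfg: SimulationConfig, coal_scale: float) -> _SimNode:
    tips = [_SimNode(0.0, label=lab) for lab in labels]
    cap = 0.95 * cfg.t_split
    if cfg.n_regions_per_clade == 1:
        root = _kingman(rng, tips, coal_scale, 0.0)
        _rescale_below(root, cap)
        return root
    t_region = cfg.region_split_fraction * cfg.t_split
    chunks = np.array_split(np.arange(len(tips)), cfg.n_regions_per_clade)
    region_roots = []
    for chunk in chunks:
        sub = [tips[i] for i in chunk]
        root = _kingman(rng, sub, coal_scale, 0.0)
        _rescale_below(root, 0.95 * t_region)
        region_roots.append(root)
    return _SimNode(t_region, region_roots)


def _evolve(rng, root: _SimNode, locus: LocusConfig, root_time: float) -> dict[str, str]:
    """Evolve sequences down the genealogy; returns label -> residues."""
    model = TN93Model(locus.tn93)
    pi = np.asarray(locus.tn93.pi)
    length = locus.length
    if locus.gamma_shape is not None:
        site_rates = rng.gamma(locus.gamma_shape, 1.0 / locus.gamma_shape, size=length)
    else:
        site_rates = np.ones(length)
    s_rate = locus.substitution_rate
    root_seq = rng.choice(4, size=length, p=pi)
    out: dict[str, str] = {}
    base_arr = np.array(list(BASES))

    def descend(node: _SimNode, parent_time: float, seq: np.ndarray):
        dt = parent_time - node.time
        blen = dt * s_rate * node.pendant_scale
        if blen > 0:
            pmats = model.transition_probs(blen * site_rates)  # (L, 4, 4)
            probs = pmats[np.arange(length), seq, :]
            cdf = np.cumsum(probs, axis=1)
            cdf[:, -1] = 1.0
            u = rng.random(length)
            child_seq = (u[:, None] > cdf).sum(axis=1).astype(np.int8)
        else:
            child_seq = seq.copy()
        if node.label is not None:
            out[node.label] = "".join(base_arr[child_seq])
        for c in node.children:
            descend(c, node.time, child_seq)

    descend(root, root_time, root_seq)
    return out


def _true_newick(root: _SimNode, root_time: float, s_rate: float) -> str:
    def fmt(node: _SimNode, parent_time: float) -> str:
        blen = (parent_time - node.time) * s_rate * node.pendant_scale
        if node.label is not None:
            return f"{node.label}:{blen:.10f}"
        inner = ",".join(fmt(c, node.time) for c in node.children)
        return f"({inner}):{blen:.10f}"

    inner = ",".join(fmt(c, root.time) for c in root.children)
    return f"({inner});"


def _simulate(
    cfg: SimulationConfig, accel_lineage: str | None, factor: float
) -> tuple[dict[str, Alignment], GroupPartition, dict]:
    rng = np.random.default_rng(cfg.seed)
    prefixes = ("wa", "ep")
    labels_by_clade = [
        [f"{p}{i + 1:02d}" for i in range(cfg.n_per_clade)] for p in prefixes
    ]
    all_labels = [lab for clade in labels_by_clade for lab in clade]
    if accel_lineage is not None and accel_lineage not in all_labels:
        raise ConfigError(f"unknown lineage {accel_lineage!r}; samples are {all_labels}")

    s_ref = cfg.loci[0].substitution_rate
    coal_scale = cfg.intra_clade_theta / (2.0 * s_ref) if s_ref > 0 else 0.0

    assignments: dict[str, tuple[str, str]] = {}
    for clade_i, (group, labels) in enumerate(zip(cfg.group_labels, labels_by_clade)):
        chunks = np.array_split(np.arange(len(labels)), cfg.n_regions_per_clade)
        for r, chunk in enumerate(chunks):
            region = group if cfg.n_regions_per_clade == 1 else f"{group}_r{r + 1}"
            for i in chunk:
                assignments[labels[i]] = (group, region)
    partition = GroupPartition(assignments)

    alignments: dict[str, Alignment] = {}
    truth: dict = {
        "t_split": cfg.t_split,
        "seed": cfg.seed,
        "intra_clade_theta": cfg.intra_clade_theta,
        "loci": {},
        "trees": {},
        "accel_lineage": accel_lineage,
        "accel_factor": factor if accel_lineage else None,
    }
    for locus in cfg.loci:
        clade_roots = [
            _clade_genealogy(rng, labels, cfg, coal_scale) for labels in labels_by_clade
        ]
        root = _SimNode(cfg.t_split, clade_roots)
        if accel_lineage is not None:
            stack = [root]
            while stack:
                n = stack.pop()
                if n.label == accel_lineage:
                    n.pendant_scale = factor
                stack.extend(n.children)
        seqs = _evolve(rng, root, locus, root_time=cfg.t_split)
        records = [SequenceRecord(lab, seqs[lab]) for lab in all_labels]
        alignments[locus.name] = Alignment(locus.name, records)
        truth["loci"][locus.name] = {
            "length": locus.length,
            "divergence_rate": locus.divergence_rate,
            "substitution_rate": locus.substitution_rate,
            "kappa1": locus.tn93.kappa1,
            "kappa2": locus.tn93.kappa2,
            "pi": list(locus.tn93.pi),
            "gamma_shape": locus.gamma_shape,
        }
        truth["trees"][locus.name] = _true_newick(
            root, cfg.t_split, locus.substitution_rate
        )
    return alignments, partition, truth


def simulate_geminate(cfg: SimulationConfig):
    """Simulate a geminate-pair dataset under a strict molecular clock.

    Returns ``(alignments, partition, truth)`` where ``alignments`` maps
    locus name to :class:`Alignment`, ``partition`` labels each sample
    with its clade (and region), and ``truth`` records the generating
    parameters and the true genealogies (Newick, substitutions/site).
    """
    return _simulate(cfg, None, 1.0)


def simulate_clock_violation(cfg: SimulationConfig, accel_lineage: str, factor: float):
    """As :func:`simulate_geminate` but one sample's pendant branch rate
    is multiplied by ``factor`` (0 makes it identical to its ancestor)."""
    if factor < 0:
        raise ConfigError("factor must be >= 0")
    return _simulate(cfg, accel_lineage, factor)
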