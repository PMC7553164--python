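"""Longitudinal differentiation simulator with batch effects.

Emulates a time-course single-cell experiment over a small differentiation
tree: stem cells S branch into multipotent types A and B, which branch
into terminal types A1/A2 and B1/B2.  Each type has an ideal nonnegative
expression-rate profile; cells partway along an edge parent -> child get
the convex interpolation

    theta * parent + (1 - theta) * child,        theta in [0, 1],

with theta drawn uniformly from a window that slides from the parent end
toward the child end as sampling day increases.  A random subset of genes
is "susceptible to the batch effect": each sample adds its own additive
offset to those genes.  Per-cell Gaussian noise perturbs the rate vector,
rates are floored at zero, and counts are drawn from a Poisson.

The generator emits the counts plus per-cell ground truth (sample, day,
type label, theta) for evaluating batch-correction methods.  Cells with
theta near 0.5 get transitional labels like ``"A->A1"``; cells close to
either end get the pure-type label.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import CountMatrix

__all__ = [
    "CellTypeTree",
    "CompositionEntry",
    "SampleSpec",
    "SampleDesign",
    "BatchEffectSpec",
    "TYPE_VOCABULARY",
    "interpolate_profile",
    "label_for_theta",
    "default_tree",
    "default_config",
    "generate_dataset",
]

TYPE_VOCABULARY = (
    "S", "S->A", "S->B", "A", "B",
    "A->A1", "A->A2", "B->B1", "B->B2",
    "A1", "A2", "B1", "B2",
)


@dataclass
class CellTypeTree:
    """Differentiation tree: per-type ideal rate profiles plus edges."""

    profiles: dict[str, np.ndarray]
    edges: list[tuple[str, str]]

    def __post_init__(self):
        lengths = set()
        for name, prof in self.profiles.items():
            prof = np.asarray(prof, dtype=float)
            if prof.ndim != 1 or (prof < 0).any():
                raise ValueError(f"profile for {name!r} must be 1-D and nonnegative")
            self.profiles[name] = prof
            lengths.add(prof.shape[0])
        if len(lengths) != 1:
            raise ValueError("all profiles must have the same length")
        children = [c for _, c in self.edges]
        if len(set(children)) != len(children):
            raise ValueError("a type has more than one parent (not a tree)")
        for p, c in self.edges:
            if p not in self.profiles or c not in self.profiles:
                raise ValueError(f"edge ({p}, {c}) references an unknown type")
        roots = set(self.profiles) - set(children)
        if len(roots) != 1:
            raise ValueError(f"expected a single root, found {sorted(roots)}")

    @property
    def root(self) -> str:
        children = {c for _, c in self.edges}
        return next(iter(set(self.profiles) - children))

    @property
    def n_genes(self) -> int:
        return next(iter(self.profiles.values())).shape[0]


@dataclass
class CompositionEntry:
    """One component of a sample: a pure type or an edge with a theta range.

    ``child=None`` denotes cells of the pure ``parent`` type; otherwise
    cells sit on the edge parent -> child with theta drawn uniformly from
    ``theta_range`` (theta=1 is the parent end).
    """

    parent: str
    child: str | None
    fraction: float
    theta_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        lo, hi = self.theta_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"theta_range must lie within [0, 1], got {self.theta_range}")
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError(f"fraction must lie in [0, 1], got {self.fraction}")


@dataclass
class SampleSpec:
    sample_id: str
    day: float
    composition: list[CompositionEntry]

    def __post_init__(self):
        total = sum(e.fraction for e in self.composition)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"sample {self.sample_id!r}: composition fractions sum to "
                f"{total}, expected 1"
            )


@dataclass
class SampleDesign:
    samples: list[SampleSpec]
    n_cells_per_sample: int = 500

    def __post_init__(self):
        if self.n_cells_per_sample < 1:
            raise ValueError("n_cells_per_sample must be >= 1")
        days = [s.day for s in self.samples]
        if any(b < a for a, b in zip(days, days[1:])):
            raise ValueError("samples must be listed in nondecreasing day order")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique")


@dataclass
class BatchEffectSpec:
    """Additive per-sample offsets on a random susceptible gene subset.

    Offsets are drawn N(0, effect_scale) independently per (sample, gene).
    ``seed=None`` derives the susceptible set and offsets from the
    dataset-level seed; set it to decouple the batch structure from the
    per-cell draws.
    """

    n_susceptible_genes: int = 50
    effect_scale: float = 3.0
    seed: int | None = None

    def __post_init__(self):
        if self.n_susceptible_genes < 0:
            raise ValueError("n_susceptible_genes must be >= 0")
        if self.effect_scale < 0:
            raise ValueError("effect_scale must be >= 0")


def interpolate_profile(parent_profile, child_profile, theta: float) -> np.ndarray:
    """Convex combination theta*parent + (1-theta)*child, elementwise."""
    parent = np.asarray(parent_profile, dtype=float)
    child = np.asarray(child_profile, dtype=float)
    if parent.shape != child.shape:
        raise ValueError("parent and child profiles must have equal length")
    if (parent < 0).any() or (child < 0).any():
        raise ValueError("profiles must be nonnegative")
    if not (0.0 <= theta <= 1.0):
        raise ValueError(f"theta must lie in [0, 1], got {theta}")
    return theta * parent + (1.0 - theta) * child


def label_for_theta(
    parent: str, child: str, theta: float, lo: float = 1 / 3, hi: float = 2 / 3
) -> str:
    """Type label along an edge: parent above ``hi``, child below ``lo``,
    transitional ``"parent->child"`` in between."""
    if theta > hi:
        return parent
    if theta < lo:
        return child
    return f"{parent}->{child}"


# Profile construction constants: baseline expression rate, per-type marker
# block size and elevation, and the decay of inherited ancestor markers per
# tree step.  Chosen so adjacent tree types overlap in inherited markers
# (gradual differentiation) while each type stays identifiable.
_BASELINE = 1.0
_MARKER_RATE = 8.0
_INHERIT_DECAY = 0.4
_MARKERS_PER_TYPE = 20


def default_tree(n_genes: int = 200) -> CellTypeTree:
    """The seven-type tree S -> {A, B}, A -> {A1, A2}, B -> {B1, B2}.

    Each type carries a disjoint block of marker genes elevated to
    ``_MARKER_RATE`` above a flat baseline; a type also inherits its
    ancestors' markers, attenuated by ``_INHERIT_DECAY`` per step, so
    parent and child profiles are correlated along the tree.
    """
    order = ["S", "A", "B", "A1", "A2", "B1", "B2"]
    if n_genes < _MARKERS_PER_TYPE * len(order):
        raise ValueError(
            f"need at least {_MARKERS_PER_TYPE * len(order)} genes for marker blocks"
        )
    edges = [("S", "A"), ("S", "B"), ("A", "A1"), ("A", "A2"), ("B", "B1"), ("B", "B2")]
    parent_of = {c: p for p, c in edges}
    blocks = {
        t: np.arange(i * _MARKERS_PER_TYPE, (i + 1) * _MARKERS_PER_TYPE)
        for i, t in enumerate(order)
    }
    profiles: dict[str, np.ndarray] = {}
    for t in order:
        prof = np.full(n_genes, _BASELINE)
        node, boost = t, _MARKER_RATE
        while node is not None:
            prof[blocks[node]] += boost
            node = parent_of.get(node)
            boost *= _INHERIT_DECAY
        profiles[t] = prof
    return CellTypeTree(profiles=profiles, edges=edges)


# theta windows by developmental stage: early samples sit near the parent
# end of an edge (theta near 1), late samples near the child end.
_EARLY = (0.75, 1.0)
_MID = (0.25, 0.75)
_LATE = (0.0, 0.25)


def default_config(
    n_cells_per_sample: int = 500,
    n_genes: int = 200,
    n_susceptible_genes: int = 50,
    effect_scale: float = 3.0,
    day1_second_edge: tuple[str, str] = ("S", "A"),
) -> tuple[CellTypeTree, SampleDesign, BatchEffectSpec]:
    """The packaged seven-sample, 200-gene longitudinal benchmark design.

    One sample on day 1 (80% pure S, 20% early S->A), two samples on each
    of days 2-4.  Day-2 samples mix the S->A and S->B edges mid-transition;
    days 3-4 spread evenly over the four terminal edges, mid-transition on
    day 3 and near-terminal on day 4.  Same-day samples share a
    composition, so any per-sample split of a cell type is pure batch
    effect.  ``day1_second_edge`` overrides which edge carries the day-1
    20% component.
    """
    tree = default_tree(n_genes)
    p, c = day1_second_edge
    terminal = [("A", "A1"), ("A", "A2"), ("B", "B1"), ("B", "B2")]

    def fan(window):
        return [CompositionEntry(p_, c_, 0.25, window) for p_, c_ in terminal]

    samples = [
        SampleSpec("d1_s1", 1.0, [
            CompositionEntry("S", None, 0.8),
            CompositionEntry(p, c, 0.2, _EARLY),
        ]),
        SampleSpec("d2_s1", 2.0, [
            CompositionEntry("S", "A", 0.5, _MID),
            CompositionEntry("S", "B", 0.5, _MID),
        ]),
        SampleSpec("d2_s2", 2.0, [
            CompositionEntry("S", "A", 0.5, _MID),
            CompositionEntry("S", "B", 0.5, _MID),
        ]),
        SampleSpec("d3_s1", 3.0, fan(_MID)),
        SampleSpec("d3_s2", 3.0, fan(_MID)),
        SampleSpec("d4_s1", 4.0, fan(_LATE)),
        SampleSpec("d4_s2", 4.0, fan(_LATE)),
    ]
    design = SampleDesign(samples=samples, n_cells_per_sample=n_cells_per_sample)
    batch = BatchEffectSpec(
        n_susceptible_genes=n_susceptible_genes, effect_scale=effect_scale
    )
    return tree, design, batch


def _exact_allocation(fractions: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder apportionment of n cells to composition entries."""
    raw = fractions * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def generate_dataset(
    tree: CellTypeTree,
    design: SampleDesign,
    batch: BatchEffectSpec,
    noise_sd: float = 0.5,
    seed: int = 0,
    allocation: str = "exact",
    label_thresholds: tuple[float, float] = (1 / 3, 2 / 3),
    return_info: bool = False,
):
    """Draw the full count matrix plus ground truth, reproducibly.

    Returns ``(counts, truth)`` where ``truth`` has one row per cell with
    columns ``cell_id, sample, day, type, theta`` (theta is NaN for
    pure-type cells).  ``allocation="exact"`` apportions composition
    fractions deterministically; ``"multinomial"`` draws them.  With
    ``return_info`` a third element exposes the susceptible gene indices
    and the per-sample additive offsets actually applied.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if allocation not in ("exact", "multinomial"):
        raise ValueError(f"unknown allocation mode {allocation!r}")
    g = tree.n_genes
    if batch.n_susceptible_genes > g:
        raise ValueError("n_susceptible_genes exceeds the number of genes")

    ss = np.random.SeedSequence(seed)
    cells_ss, struct_ss = ss.spawn(2)
    rng_cells = np.random.default_rng(cells_ss)
    rng_struct = np.random.default_rng(
        batch.seed if batch.seed is not None else struct_ss
    )

    susceptible = rng_struct.choice(g, size=batch.n_susceptible_genes, replace=False)
    offsets = rng_struct.normal(
        0.0, batch.effect_scale, size=(len(design.samples), batch.n_susceptible_genes)
    )

    lo_t, hi_t = label_thresholds
    blocks: list[np.ndarray] = []
    records: list[dict] = []
    for si, spec in enumerate(design.samples):
        fractions = np.array([e.fraction for e in spec.composition])
        n = design.n_cells_per_sample
        if allocation == "exact":
            counts_per_entry = _exact_allocation(fractions, n)
        else:
            counts_per_entry = rng_cells.multinomial(n, fractions)
        for entry, m in zip(spec.composition, counts_per_entry):
            if m == 0:
                continue
            if entry.child is None:
                rates = np.tile(tree.profiles[entry.parent], (m, 1))
                thetas = np.full(m, np.nan)
                labels = [entry.parent] * m
            else:
                lo, hi = entry.theta_range
                thetas = rng_cells.uniform(lo, hi, size=m)
                parent = tree.profiles[entry.parent]
                child = tree.profiles[entry.child]
                rates = thetas[:, None] * parent + (1.0 - thetas)[:, None] * child
                labels = [
                    label_for_theta(entry.parent, entry.child, t, lo_t, hi_t)
                    for t in thetas
                ]
            rates = rates.copy()
            rates[:, susceptible] += offsets[si]
            if noise_sd > 0:
                rates += rng_cells.normal(0.0, noise_sd, size=rates.shape)
            np.clip(rates, 0.0, None, out=rates)
            blocks.append(rng_cells.poisson(rates).astype(float))
            for t, lab in zip(thetas, labels):
                records.append(
                    {
                        "cell_id": f"{spec.sample_id}_c{len(records):05d}",
                        "sample": spec.sample_id,
                        "day": spec.day,
                        "type": lab,
                        "theta": t,
                    }
                )
    truth = pd.DataFrame.from_records(records)
    counts = CountMatrix(
        np.vstack(blocks),
        cell_ids=truth["cell_id"].to_numpy(dtype=object),
        gene_ids=np.array([f"gene{i:03d}" for i in range(g)], dtype=object),
    )
    if return_info:
        return counts, truth, {"susceptible": susceptible, "offsets": offsets}
    return counts, truth
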