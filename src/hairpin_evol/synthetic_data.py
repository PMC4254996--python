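"""Simulation of hairpin sequence evolution under stem-pairing constraint.

The generator produces, from a single seed, everything the analysis
pipeline consumes: an ultrametric tree (Yule by default, or any supplied
Newick), a hairpin-locus alignment whose stem positions evolve under a
pairing-class acceptance filter, a linked fully neutral reference locus on
the same tree, the true structure, and an event log.

Mechanism
---------
Substitutions are proposed under JC69 (every site at rate ``mu``
proposals per unit branch length, target base uniform among the three
alternatives) with exact exponential waiting times per branch.  At
unpaired sites every proposal is accepted.  At paired sites the proposal
is accepted with the weight of the *resulting* pair class:

    Watson-Crick -> w_wc (fixed at 1),  wobble -> w_wobble,
    mismatch     -> w_mismatch.

This is a rejection-sampling caricature of purifying selection on stem
pairing: random mutation, structure-filtered inheritance.  With
probability ``compensatory_rate`` an accepted stem change that does not
itself restore Watson-Crick pairing is immediately accompanied by the
partner substitution that does — the co-evolutionary double substitution.

Indels occur only in the terminal loop (at most one deletion per branch,
length uniform in ``indel_length_range``), mirroring hairpins whose arms
tolerate no indels while the loop does.  Deletions are recorded as gap
characters so all rows stay aligned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .alignment_io import (
    AlignmentError,
    FormatError,
    MultipleAlignment,
    Role,
    SequenceRecord,
    complement,
    parse_newick,
)
from .hairpin_fold import HairpinPartition, SecondaryStructure, can_pair
from .struct_classify import PairClass, pair_class

BASES = "ACGT"


# ---------------------------------------------------------------------------
# Trees


@dataclass(eq=False)
class _Node:
    length: float = 0.0  # branch above this node
    name: Optional[str] = None
    children: list["_Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["_Node"]:
        if self.is_leaf:
            return [self]
        out = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.length:.8f}"
        inner = ",".join(c._newick_inner() for c in self.children)
        return f"({inner}):{self.length:.8f}"


def generate_tree(
    seed: int,
    n_taxa: int,
    birth_rate: float = 1.0,
    height: float = 1.0,
    label_prefix: str = "taxon",
) -> str:
    """Ultrametric Yule tree as a Newick string, deterministic from *seed*."""
    rng = np.random.default_rng(seed)
    return _yule_tree(rng, n_taxa, birth_rate, height, label_prefix).newick()


def _yule_tree(
    rng: np.random.Generator,
    n_taxa: int,
    birth_rate: float,
    height: float,
    label_prefix: str = "taxon",
) -> _Node:
    if n_taxa < 2:
        raise AlignmentError("a tree needs at least 2 taxa")
    if birth_rate <= 0 or height <= 0:
        raise AlignmentError("birth_rate and height must be positive")
    root = _Node()
    start_time = {root: 0.0}
    active = [root]
    t = 0.0
    # root splits immediately into two lineages; then pure-birth until n
    first = [_Node(), _Node()]
    root.children = first
    for c in first:
        start_time[c] = 0.0
    active = list(first)
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        idx = rng.integers(len(active))
        parent = active.pop(int(idx))
        parent.length = t - start_time[parent]
        kids = [_Node(), _Node()]
        parent.children = kids
        for k in kids:
            start_time[k] = t
        active.extend(kids)
    t_end = t + rng.exponential(1.0 / (birth_rate * n_taxa))
    for leaf in active:
        leaf.length = t_end - start_time[leaf]
    width = len(str(n_taxa))
    for i, leaf in enumerate(root.leaves(), start=1):  # preorder: deterministic
        leaf.name = f"{label_prefix}{i:0{width}d}"
    _scale_tree(root, height / t_end)
    return root


def _scale_tree(node: _Node, factor: float) -> None:
    node.length *= factor
    for child in node.children:
        _scale_tree(child, factor)


def _node_from_newick(newick: str) -> _Node:
    tree = parse_newick(newick)

    def convert(dnode) -> _Node:
        node = _Node(
            length=float(dnode.edge.length or 0.0),
            name=dnode.taxon.label.replace(" ", "_") if dnode.taxon else None,
        )
        node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    root = convert(tree.seed_node)
    leaves = root.leaves()
    if any(leaf.name is None for leaf in leaves):
        raise FormatError("every leaf in the supplied tree must be labelled")
    if len(leaves) < 2:
        raise FormatError("supplied tree has fewer than 2 leaves")
    return root


def total_tree_length(newick: str) -> float:
    root = _node_from_newick(newick)

    def walk(node: _Node) -> float:
        return node.length + sum(walk(c) for c in node.children)

    return walk(root) - root.length


# ---------------------------------------------------------------------------
# Default hairpin template


def paper_like_structure(
    length: int = 214,
    arm5_end: int = 73,
    loop_end: int = 139,
    bulges: tuple[int, ...] = (150, 170),
) -> SecondaryStructure:
    """A hairpin with a fully paired 5' arm, an unpaired terminal loop and a
    3' arm carrying unpaired bulges that absorb the arm-length difference.

    The defaults give a 214-nt hairpin partitioned 73/66/75 with stem
    pairs (1, 214) ... (73, 140), the layout of a typical plant pre-miRNA
    alignment this package targets.
    """
    arm3_positions = [p for p in range(length, loop_end, -1) if p not in bulges]
    n5 = arm5_end
    if len(arm3_positions) != n5:
        raise AlignmentError(
            f"arm lengths inconsistent: 5' arm has {n5} sites but the 3' arm "
            f"offers {len(arm3_positions)} pairable positions"
        )
    pairs = [(i, arm3_positions[i - 1]) for i in range(1, n5 + 1)]
    return SecondaryStructure.from_pairs(length, pairs)


def default_partition() -> HairpinPartition:
    return HairpinPartition.fixed(214, arm5_end=73, loop_end=139)


# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class SimulationConfig:
    """Study-like defaults: 45 taxa, a 214-nt hairpin split 73/66/75, a
    266-nt neutral locus, strong stem constraint with frequent compensation.

    ``mu`` is the per-site proposal rate per unit branch length; the
    default is calibrated so the neutral locus shows Watterson theta near
    0.09-0.11 on the default tree, the diversity scale of a fast-evolving
    nuclear spacer.
    """

    seed: int = 0
    n_taxa: int = 45
    tree: Optional[str] = None  # Newick; generated (Yule) when None
    birth_rate: float = 1.0
    tree_height: float = 1.0
    mu: float = 0.042
    structure: Optional[SecondaryStructure] = None  # default: paper_like_structure()
    w_wobble: float = 0.05
    w_mismatch: float = 0.05
    compensatory_rate: float = 0.5
    loop_indel_rate: float = 0.02
    indel_length_range: tuple[int, int] = (1, 10)
    neutral_locus_length: int = 266
    n_outgroups: int = 0
    outgroup_branch: float = 0.5  # in tree-height units

    def __post_init__(self) -> None:
        for name in ("w_wobble", "w_mismatch", "compensatory_rate", "loop_indel_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise AlignmentError(f"{name} must be in [0, 1], got {v}")
        if self.n_taxa < 2:
            raise AlignmentError("n_taxa must be >= 2")
        if self.mu <= 0:
            raise AlignmentError("mu must be positive")
        lo, hi = self.indel_length_range
        if not (1 <= lo <= hi):
            raise AlignmentError("invalid indel_length_range")

    @property
    def weights(self) -> dict[PairClass, float]:
        return {
            PairClass.WATSON_CRICK: 1.0,
            PairClass.WOBBLE: self.w_wobble,
            PairClass.MISMATCH: self.w_mismatch,
        }


@dataclass(frozen=True)
class SimulatedDataset:
    alignment: MultipleAlignment  # hairpin locus (ingroup + any outgroups)
    neutral_alignment: MultipleAlignment  # same taxa, unconstrained locus
    true_tree: str  # Newick
    true_structure: SecondaryStructure
    event_log: tuple[dict, ...]

    @property
    def n_rejected(self) -> int:
        return sum(1 for e in self.event_log if not e["accepted"])

    @property
    def n_accepted(self) -> int:
        return sum(1 for e in self.event_log if e["accepted"])


# ---------------------------------------------------------------------------
# The simulator


def _random_root(rng: np.random.Generator, structure: SecondaryStructure) -> list[str]:
    """Root hairpin sequence exactly compatible with the structure: paired
    positions carry Watson-Crick partners, the rest uniform."""
    seq = [BASES[int(rng.integers(4))] for _ in range(structure.length)]
    for i, j in structure.pairs():
        seq[j - 1] = complement(seq[i - 1])
    return seq


def _mutate_branch(
    rng: np.random.Generator,
    seq: list[str],
    length: float,
    mu: float,
    partner: Optional[Sequence[int]],  # 0-based partner index or -1; None = neutral
    weights: Optional[dict[PairClass, float]],
    compensatory_rate: float,
    lineage: str,
    locus: str,
    log: list[dict],
) -> None:
    """Apply the JC69 proposal / pair-class acceptance process in place."""
    L = len(seq)
    n_events = rng.poisson(mu * L * length)
    for _ in range(n_events):
        site = int(rng.integers(L))
        old = seq[site]
        if old == "-":
            continue
        new = BASES[(BASES.index(old) + 1 + int(rng.integers(3))) % 4]
        entry = {
            "lineage": lineage,
            "locus": locus,
            "site": site + 1,
            "from": old,
            "to": new,
            "pair_class": None,
            "accepted": True,
            "compensatory": False,
        }
        j = partner[site] if partner is not None else -1
        if j >= 0:
            outcome = pair_class(new.replace("T", "U"), seq[j].replace("T", "U"))
            entry["pair_class"] = outcome.value
            if rng.random() >= weights[outcome]:
                entry["accepted"] = False
                log.append(entry)
                continue
            seq[site] = new
            if outcome != PairClass.WATSON_CRICK and rng.random() < compensatory_rate:
                restored = complement(new)
                log.append(entry)
                log.append(
                    {
                        "lineage": lineage,
                        "locus": locus,
                        "site": j + 1,
                        "from": seq[j],
                        "to": restored,
                        "pair_class": PairClass.WATSON_CRICK.value,
                        "accepted": True,
                        "compensatory": True,
                    }
                )
                seq[j] = restored
                continue
        else:
            seq[site] = new
        log.append(entry)


def _apply_loop_indel(
    rng: np.random.Generator,
    seq: list[str],
    loop_start: int,
    loop_end: int,
    length_range: tuple[int, int],
    lineage: str,
    log: list[dict],
) -> None:
    lo, hi = length_range
    size = int(rng.integers(lo, hi + 1))
    live = [i for i in range(loop_start - 1, loop_end) if seq[i] != "-"]
    if not live:
        return
    size = min(size, len(live))
    start_idx = int(rng.integers(len(live) - size + 1))
    targets = live[start_idx : start_idx + size]
    for i in targets:
        seq[i] = "-"
    log.append(
        {
            "lineage": lineage,
            "locus": "hairpin",
            "site": targets[0] + 1,
            "from": "indel",
            "to": f"del{len(targets)}",
            "pair_class": None,
            "accepted": True,
            "compensatory": False,
        }
    )


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Run the full two-locus simulation; byte-reproducible from the seed."""
    rng = np.random.default_rng(config.seed)

    structure = config.structure or paper_like_structure()
    try:
        partition = (
            default_partition()
            if config.structure is None
            else None
        )
    except AlignmentError:
        partition = None

    if config.tree is not None:
        root = _node_from_newick(config.tree)
        newick = config.tree
    else:
        root = _yule_tree(rng, config.n_taxa, config.birth_rate, config.tree_height)
        newick = root.newick()

    partner = [(-1 if p is None else p - 1) for p in structure.pair_of]
    # loop bounds for indels: the unpaired span between the innermost pair
    pairs = structure.pairs()
    innermost = max(pairs, key=lambda p: p[0])
    loop_start, loop_end = innermost[0] + 1, innermost[1] - 1

    root_hairpin = _random_root(rng, structure)
    root_neutral = [BASES[int(rng.integers(4))] for _ in range(config.neutral_locus_length)]

    log: list[dict] = []
    hairpin_rows: dict[str, str] = {}
    neutral_rows: dict[str, str] = {}

    counter = {"n": 0}

    def descend(node: _Node, hp: list[str], nt: list[str]) -> None:
        for child in node.children:
            counter["n"] += 1
            label = child.name or f"node{counter['n']}"
            child_hp = list(hp)
            child_nt = list(nt)
            _mutate_branch(
                rng, child_hp, child.length, config.mu, partner, config.weights,
                config.compensatory_rate, label, "hairpin", log,
            )
            if rng.random() < config.loop_indel_rate:
                _apply_loop_indel(
                    rng, child_hp, loop_start, loop_end,
                    config.indel_length_range, label, log,
                )
            _mutate_branch(
                rng, child_nt, child.length, config.mu, None, None, 0.0,
                label, "neutral", log,
            )
            if child.is_leaf:
                hairpin_rows[child.name] = "".join(child_hp)
                neutral_rows[child.name] = "".join(child_nt)
            else:
                descend(child, child_hp, child_nt)

    descend(root, root_hairpin, root_neutral)

    records = [
        SequenceRecord(id=name, seq=hairpin_rows[name], role=Role.INGROUP)
        for name in sorted(hairpin_rows)
    ]
    neutral_records = [
        SequenceRecord(id=name, seq=neutral_rows[name], role=Role.INGROUP)
        for name in sorted(neutral_rows)
    ]

    for k in range(config.n_outgroups):
        label = f"outgroup{k + 1}"
        og_hp = list(root_hairpin)
        og_nt = list(root_neutral)
        branch = config.outgroup_branch * config.tree_height
        _mutate_branch(
            rng, og_hp, branch, config.mu, partner, config.weights,
            config.compensatory_rate, label, "hairpin", log,
        )
        _mutate_branch(rng, og_nt, branch, config.mu, None, None, 0.0, label, "neutral", log)
        records.append(SequenceRecord(id=label, seq="".join(og_hp), role=Role.OUTGROUP))
        neutral_records.append(
            SequenceRecord(id=label, seq="".join(og_nt), role=Role.OUTGROUP)
        )

    return SimulatedDataset(
        alignment=MultipleAlignment(tuple(records)),
        neutral_alignment=MultipleAlignment(tuple(neutral_records)),
        true_tree=newick,
        true_structure=structure,
        event_log=tuple(log),
    )


# ---------------------------------------------------------------------------
# Small direct simulators (used as oracles for the distance and rate tests)


def evolve_jc69(rng: np.random.Generator, seq: str, d: float) -> str:
    """Evolve a sequence for *d* expected substitutions/site under JC69.

    Vectorised: a site changes with probability 1 - P(same), and a changed
    site picks one of the three alternative bases uniformly.
    """
    lookup = np.full(128, -1, dtype=np.int64)
    for i, b in enumerate(BASES):
        lookup[ord(b)] = i
    idx = lookup[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (idx < 0).any():
        raise AlignmentError("evolve_jc69 requires an ungapped A/C/G/T sequence")
    p_same, _ = _jc69_site_probs(d)
    change = rng.random(len(idx)) < (1.0 - p_same)
    offsets = rng.integers(1, 4, size=int(change.sum()))
    idx[change] = (idx[change] + offsets) % 4
    base_arr = np.frombuffer("".join(BASES).encode(), dtype=np.uint8)
    return base_arr[idx].tobytes().decode()


def _jc69_site_probs(d: float) -> tuple[float, float]:
    e = math.exp(-4.0 * d / 3.0)
    return 0.25 + 0.75 * e, 0.25 - 0.25 * e


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[int(i)] for i in rng.integers(4, size=length))


def simulate_triplet_jc69(
    rng: np.random.Generator, length: int, a: float, b: float, o: float
) -> tuple[str, str, str]:
    """Three sequences radiating from a uniform-random ancestor with branch
    lengths (a, b, o) — the null-model generator for the relative-rate test."""
    anc = random_sequence(rng, length)
    return (
        evolve_jc69(rng, anc, a),
        evolve_jc69(rng, anc, b),
        evolve_jc69(rng, anc, o),
    )
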