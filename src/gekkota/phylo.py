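"""Distance trees, reference placement, and strict-clock expansion dating.

The gene-family analyses need three things from phylogenetics, all at desk
scale: (i) a tree over family members, built by neighbor joining on p- or
Poisson-corrected distances and midpoint-rooted; (ii) a subgroup label for a
query sequence (olfactory-receptor classes, opsin paralogs) taken from its
nearest labelled reference; (iii) absolute ages for duplication nodes, from
branch lengths in substitutions/site converted with a single clock rate
anchored on fossil-calibrated nodes (for setae beta-keratins: the ~156 Myr
bird scale/claw keratin divergence and the 66-51 Myr feather keratin
expansion).

Dating is the minimal strict-clock reading of "divergence value of the branch
site": a node's depth is the mean path length from the node to its leaves,
a single rate is fit by least squares through the origin over the calibration
nodes (depth = rate x age), and every duplication node's age is depth/rate.
Expansion bursts are maximal runs of node ages whose consecutive gaps do not
exceed ``max_gap`` million years.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import yaml

__all__ = [
    "CalibrationPoint",
    "ExpansionReport",
    "PlacementResult",
    "ReferenceSeq",
    "pairwise_distance",
    "p_distance",
    "neighbor_joining",
    "classify_by_placement",
    "node_depth",
    "fit_rate",
    "date_expansions",
    "read_tree",
    "write_tree",
    "read_calibrations",
]

GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class CalibrationPoint:
    """A named-node age constraint: the MRCA of ``mrca_of`` is ``age`` Myr old.

    ``age`` may be a point value or an ``(lo, hi)`` interval; intervals are
    resolved to the midpoint by default.
    """

    mrca_of: frozenset[str]
    age: float | tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.mrca_of) < 2:
            raise ValueError("calibration needs at least two leaf names")
        if isinstance(self.age, tuple):
            lo, hi = self.age
            if not (0 < lo <= hi):
                raise ValueError("calibration interval must satisfy 0 < lo <= hi")
        elif self.age <= 0:
            raise ValueError("calibration age must be positive")

    def resolve_age(self, interval_mode: str = "midpoint") -> float:
        if not isinstance(self.age, tuple):
            return float(self.age)
        lo, hi = self.age
        if interval_mode == "midpoint":
            return 0.5 * (lo + hi)
        if interval_mode == "lo":
            return float(lo)
        if interval_mode == "hi":
            return float(hi)
        raise ValueError(f"unknown interval mode {interval_mode!r}")


@dataclass(frozen=True)
class ExpansionReport:
    """Dated duplication nodes of a clade, grouped into bursts.

    ``ages`` is sorted descending (oldest first); ``bursts`` are
    ``(start, end, count)`` with start >= end in Myr; ``singletons`` are ages
    that belong to no run of two or more.
    """

    ages: tuple[float, ...]
    bursts: tuple[tuple[float, float, int], ...]
    singletons: tuple[float, ...]


@dataclass(frozen=True)
class ReferenceSeq:
    id: str
    label: str
    sequence: str


@dataclass(frozen=True)
class PlacementResult:
    label: str
    support: float
    nearest_id: str
    distance: float


def p_distance(a: str, b: str) -> float:
    """Proportion of mismatches over sites where neither sequence is gapped."""
    if len(a) != len(b):
        raise ValueError("sequences must be aligned (equal length)")
    compared = mismatches = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in GAP_CHARS or y in GAP_CHARS:
            continue
        compared += 1
        if x != y:
            mismatches += 1
    if compared == 0:
        raise ValueError("no comparable (ungapped) sites between sequences")
    return mismatches / compared


def pairwise_distance(
    seqs: Sequence[tuple[str, str]], model: str = "p"
) -> tuple[list[str], np.ndarray]:
    """Symmetric distance matrix over aligned sequences.

    ``model`` is ``"p"`` (p-distance) or ``"poisson"`` (-ln(1-p)); a pair with
    p >= 1 under the Poisson correction is reported as saturated.
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    ids = [i for i, _ in seqs]
    n = len(seqs)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = p_distance(seqs[i][1], seqs[j][1])
            if model == "p":
                d = p
            elif model == "poisson":
                if p >= 1.0:
                    raise ValueError(f"saturated pair ({ids[i]}, {ids[j]}): p = {p}")
                d = -math.log(1.0 - p)
            else:
                raise ValueError(f"unknown distance model {model!r}")
            mat[i, j] = mat[j, i] = d
    return ids, mat


def neighbor_joining(
    ids: Sequence[str], matrix: np.ndarray, root: str = "midpoint"
) -> dendropy.Tree:
    """Neighbor-joining tree from a distance matrix, rooted at the midpoint.

    Negative branch lengths (a standard NJ artefact on non-additive input)
    are clamped to zero with a warning.  ``root`` may instead name a leaf to
    use as outgroup.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if len(ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    dm = DistanceMatrix(np.asarray(matrix, dtype=float), list(ids))
    newick = str(nj(dm))
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    tree.is_rooted = True
    clamped = 0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
            clamped += 1
    if clamped:
        warnings.warn(f"clamped {clamped} negative NJ branch length(s) to 0")
    if root == "midpoint":
        tree.reroot_at_midpoint(update_bipartitions=True)
    else:
        og = tree.find_node_with_taxon_label(root)
        if og is None:
            raise ValueError(f"outgroup {root!r} not in tree")
        tree.to_outgroup_position(og, update_bipartitions=True)
    return tree


def classify_by_placement(
    query: str,
    references: Sequence[ReferenceSeq],
    model: str = "p",
) -> PlacementResult:
    """Subgroup label of the nearest reference, with a mean-distance margin.

    The query must already be aligned to the reference alignment (equal
    length).  Support is the margin between the best and second-best subgroup
    mean distances; a nearest-distance tie across subgroups yields the label
    ``"ambiguous"``.
    """
    if not references:
        raise ValueError("no reference sequences")
    dists = []
    for ref in references:
        p = p_distance(query, ref.sequence)
        d = -math.log(1.0 - p) if model == "poisson" else p
        dists.append(d)
    best_i = int(np.argmin(dists))
    best_d = dists[best_i]
    tied_labels = {r.label for r, d in zip(references, dists) if abs(d - best_d) < 1e-12}
    by_label: dict[str, list[float]] = {}
    for ref, d in zip(references, dists):
        by_label.setdefault(ref.label, []).append(d)
    means = sorted(np.mean(v) for v in by_label.values())
    support = float(means[1] - means[0]) if len(means) > 1 else math.inf
    label = "ambiguous" if len(tied_labels) > 1 else references[best_i].label
    return PlacementResult(
        label=label, support=support,
        nearest_id=references[best_i].id, distance=float(best_d),
    )


def node_depth(node: dendropy.Node) -> float:
    """Mean path length from ``node`` to the leaves of its subtree."""
    leaves = node.leaf_nodes()
    if node.is_leaf():
        return 0.0
    total = 0.0
    for leaf in leaves:
        d = 0.0
        cur = leaf
        while cur is not node:
            d += cur.edge.length or 0.0
            cur = cur.parent_node
        total += d
    return total / len(leaves)


def _mrca(tree: dendropy.Tree, names: Iterable[str]) -> dendropy.Node:
    node = tree.mrca(taxon_labels=list(names))
    if node is None:
        raise ValueError(f"MRCA of {sorted(names)} not resolvable in tree")
    return node


def fit_rate(
    tree: dendropy.Tree,
    calibrations: Sequence[CalibrationPoint],
    interval_mode: str = "midpoint",
) -> float:
    """Substitution rate (subst/site/Myr) from calibrated node depths.

    Least-squares slope through the origin of node depth against calibration
    age: rate = sum(depth*age) / sum(age^2).
    """
    if not calibrations:
        raise ValueError("need at least one calibration")
    num = den = 0.0
    for cal in calibrations:
        age = cal.resolve_age(interval_mode)
        depth = node_depth(_mrca(tree, cal.mrca_of))
        if age <= 0 or depth <= 0:
            raise ValueError(
                f"degenerate calibration (age={age}, depth={depth}) for {sorted(cal.mrca_of)}"
            )
        num += depth * age
        den += age * age
    return num / den


def date_expansions(
    tree: dendropy.Tree,
    rate: float,
    clade: Iterable[str],
    max_gap: float = 5.0,
) -> ExpansionReport:
    """Date every duplication node of a clade and group ages into bursts.

    The clade is the subtree under the MRCA of the given leaf names; each of
    its internal nodes is dated as depth/rate.  Bursts are maximal descending
    runs with consecutive gaps <= ``max_gap`` Myr and at least two members.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    clade = list(clade)
    if not clade:
        raise ValueError("clade must be non-empty")
    if len(clade) < 2:
        return ExpansionReport(ages=(), bursts=(), singletons=())
    top = _mrca(tree, clade)
    ages = sorted(
        (node_depth(n) / rate for n in top.preorder_iter() if not n.is_leaf()),
        reverse=True,
    )
    bursts: list[tuple[float, float, int]] = []
    singletons: list[float] = []
    run: list[float] = []
    for age in ages:
        if not run or run[-1] - age <= max_gap:
            run.append(age)
        else:
            _flush_run(run, bursts, singletons)
            run = [age]
    _flush_run(run, bursts, singletons)
    return ExpansionReport(
        ages=tuple(ages), bursts=tuple(bursts), singletons=tuple(singletons)
    )


def _flush_run(
    run: list[float],
    bursts: list[tuple[float, float, int]],
    singletons: list[float],
) -> None:
    if len(run) >= 2:
        bursts.append((run[0], run[-1], len(run)))
    elif run:
        singletons.append(run[0])


def read_tree(path: str | Path) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    tree.is_rooted = True
    return tree


def write_tree(
    tree: dendropy.Tree,
    path: str | Path,
    node_ages: dict[int, float] | None = None,
) -> None:
    """Write newick with branch lengths to 6 significant digits.

    If ``node_ages`` maps ``id(node)`` to ages, they are attached as
    ``[&age=...]`` comments on internal nodes (extended-newick dialect).
    """
    if node_ages:
        for node in tree.preorder_iter():
            if id(node) in node_ages:
                node.comments.append(f"&age={node_ages[id(node)]:.6g}")
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".6g",
    )
    with open(path, "w") as fh:
        fh.write(s)


def read_calibrations(path: str | Path) -> list[CalibrationPoint]:
    """Read calibrations from YAML: a list of ``{mrca: [A, B], age: 156}``
    blocks; ``age`` may be a two-element list for an interval."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cals = []
    for block in raw:
        age = block["age"]
        if isinstance(age, (list, tuple)):
            lo, hi = sorted(float(x) for x in age)
            age = (lo, hi)
        else:
            age = float(age)
        cals.append(CalibrationPoint(mrca_of=frozenset(block["mrca"]), age=age))
    return cals
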