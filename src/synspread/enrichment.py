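"""Over-representation tests, key-driver analysis and related statistics.

Covers the downstream systems-biology layer: hypergeometric enrichment of a
candidate gene set for marker / risk gene sets against a defined background
universe; Bonferroni and Benjamini-Hochberg multiple-testing correction;
depth-1 key-driver analysis (KDA) on a directed regulatory network, treating
edges as undirected; a chi-square goodness-of-fit test of whether key drivers
preferentially wire to key drivers of the same effect class; and the
background-corrected relative-pathology score for well-based validation
assays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "RegulatoryNetwork",
    "KDResult",
    "WellQuantification",
    "hypergeometric_enrichment",
    "adjust_pvalues",
    "key_driver_analysis",
    "kd_edge_chisquare",
    "relative_pathology",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        members = frozenset(str(m) for m in self.members)
        if not members:
            raise ValueError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "members", members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class EnrichmentResult:
    set_name: str
    overlap: int  # k
    candidate_size: int  # n
    marker_size_in_background: int  # K
    background_size: int  # N
    p_value: float
    fold_enrichment: float
    adjusted_p: float | None = None
    method: str | None = None
    flagged: bool = False


@dataclass
class RegulatoryNetwork:
    """Directed regulator -> target network over gene ids.

    Self-loops are dropped (with a count retained) and parallel edges
    collapsed on construction.
    """

    graph: nx.DiGraph
    n_self_loops_dropped: int = 0

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "RegulatoryNetwork":
        g = nx.DiGraph()
        dropped = 0
        for a, b in edges:
            a, b = str(a), str(b)
            if a == b:
                dropped += 1
                continue
            g.add_edge(a, b)
        return cls(g, dropped)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegulatoryNetwork":
        cols = list(df.columns[:2])
        return cls.from_edges(df[cols].itertuples(index=False, name=None))

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def neighborhood(self, node: str) -> set[str]:
        """Depth-1 undirected neighborhood, excluding the node itself."""
        return (set(self.graph.successors(node)) | set(self.graph.predecessors(node))) - {
            node
        }


@dataclass
class KDResult:
    node: str
    neighborhood_size: int
    overlap: int
    fold_enrichment: float
    p_value: float
    fdr: float
    is_key_driver: bool


@dataclass(frozen=True)
class WellQuantification:
    """Per-condition pathology signal and neuron-marker area from a well assay."""

    psyn_den: Mapping[str, float]  # condition -> summed integrated density
    map2_area: Mapping[str, float]  # condition -> marker-positive area

    def ratio(self, condition: str) -> float:
        area = self.map2_area[condition]
        if area <= 0:
            raise ValueError(f"MAP2 area must be > 0 for condition {condition!r}")
        den = self.psyn_den[condition]
        if den < 0:
            raise ValueError(f"pathology density must be >= 0 for {condition!r}")
        return den / area


def hypergeometric_enrichment(
    candidates: GeneSet, markers: GeneSet, background: GeneSet
) -> EnrichmentResult:
    """One-sided upper-tail hypergeometric test of candidate/marker overlap.

    Markers are intersected with the background before testing; candidates
    must be a subset of the background.  Fold enrichment is
    ``(k / n) / (K / N)``.
    """
    if not candidates.members <= background.members:
        extra = sorted(candidates.members - background.members)[:5]
        raise ValueError(f"candidates outside background, e.g. {extra}")
    n_bg = len(background)
    marker_in_bg = markers.members & background.members
    k_marker = len(marker_in_bg)
    n_cand = len(candidates)
    overlap = len(candidates.members & marker_in_bg)
    if k_marker == 0:
        return EnrichmentResult(
            markers.name, 0, n_cand, 0, n_bg, 1.0, 0.0, flagged=True
        )
    p = float(stats.hypergeom.sf(overlap - 1, n_bg, k_marker, n_cand))
    fold = (overlap / n_cand) / (k_marker / n_bg)
    return EnrichmentResult(markers.name, overlap, n_cand, k_marker, n_bg, p, fold)


def adjust_pvalues(
    ps: Sequence[float], method: str, m: int | None = None
) -> np.ndarray:
    """Bonferroni (optionally with an explicit family size) or BH step-up."""
    ps_arr = np.asarray(list(ps), dtype=float)
    if np.any((ps_arr < 0) | (ps_arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bonferroni":
        family = len(ps_arr) if m is None else int(m)
        if family < len(ps_arr):
            raise ValueError(f"family size {family} < number of tests {len(ps_arr)}")
        return np.minimum(1.0, ps_arr * family)
    if method in ("BH", "bh", "fdr_bh"):
        if m is not None and m != len(ps_arr):
            raise ValueError("BH correction uses the number of tests as family size")
        if ps_arr.size == 0:
            return ps_arr
        return multipletests(ps_arr, method="fdr_bh")[1]
    raise ValueError(f"unknown method {method!r}")


def key_driver_analysis(
    network: RegulatoryNetwork,
    candidates: GeneSet,
    fdr_threshold: float = 0.05,
) -> list[KDResult]:
    """Depth-1, direction-blind key-driver analysis.

    For every node with at least one neighbor, the undirected depth-1
    neighborhood (excluding the node itself) is tested for enrichment of the
    candidate set against all network nodes via the hypergeometric upper
    tail; BH FDR is applied across nodes and key drivers called at
    ``fdr < fdr_threshold``.  Invariant to reversing all edge directions.
    """
    if network.graph.number_of_nodes() == 0:
        raise ValueError("network is empty")
    nodes = sorted(network.nodes)
    cand_in_net = candidates.members & set(nodes)
    n_bg = len(nodes)
    k_marker = len(cand_in_net)
    rows = []
    for node in nodes:
        nb = network.neighborhood(node)
        if not nb:
            continue
        overlap = len(nb & cand_in_net)
        if k_marker == 0:
            p, fold = 1.0, 0.0
        else:
            p = float(stats.hypergeom.sf(overlap - 1, n_bg, k_marker, len(nb)))
            fold = (overlap / len(nb)) / (k_marker / n_bg)
        rows.append((node, len(nb), overlap, fold, p))
    if not rows:
        return []
    fdrs = adjust_pvalues([r[4] for r in rows], "BH")
    return [
        KDResult(
            node=node,
            neighborhood_size=size,
            overlap=overlap,
            fold_enrichment=fold,
            p_value=p,
            fdr=float(fdr),
            is_key_driver=bool(fdr < fdr_threshold),
        )
        for (node, size, overlap, fold, p), fdr in zip(rows, fdrs)
    ]


def kd_edge_chisquare(
    network: RegulatoryNetwork, kd_sets: Mapping[str, set[str]]
) -> pd.DataFrame:
    """Chi-square goodness-of-fit: do KDs wire preferentially within-effect?

    For each effect, the observation is the number of directed edges from
    that effect's key drivers to key drivers of the *same* effect, out of all
    directed edges from those sources to *any* key driver.  The expected
    same-effect count under independent target choice is
    ``total * (|KD_effect| - 1) / (|KD_any| - 1)`` (a source cannot target
    itself); the two-cell test has 1 degree of freedom.
    """
    kd_any = set().union(*kd_sets.values()) if kd_sets else set()
    unknown = kd_any - network.nodes
    if unknown:
        raise ValueError(f"key drivers absent from network: {sorted(unknown)[:5]}")
    rows = []
    for effect, sources in kd_sets.items():
        same = other = 0
        for u in sources:
            for v in network.graph.successors(u):
                if v in kd_any and v != u:
                    if v in sources:
                        same += 1
                    else:
                        other += 1
        total = same + other
        if len(kd_any) <= 1 or total == 0:
            rows.append(
                {
                    "effect": effect,
                    "observed_same": same,
                    "observed_other": other,
                    "expected_same": float("nan"),
                    "expected_other": float("nan"),
                    "chi2": float("nan"),
                    "p_value": float("nan"),
                    "status": "undefined",
                }
            )
            continue
        frac = (len(sources) - 1) / (len(kd_any) - 1)
        exp_same = total * frac
        exp_other = total - exp_same
        if exp_same == 0 or exp_other == 0:
            chi2, p = float("nan"), float("nan")
            status = "undefined"
        else:
            chi2, p = stats.chisquare([same, other], f_exp=[exp_same, exp_other])
            chi2, p, status = float(chi2), float(p), "ok"
        rows.append(
            {
                "effect": effect,
                "observed_same": same,
                "observed_other": other,
                "expected_same": exp_same,
                "expected_other": exp_other,
                "chi2": chi2,
                "p_value": p,
                "status": status,
            }
        )
    return pd.DataFrame(rows)


def relative_pathology(
    q: WellQuantification,
    treated: str = "treated",
    control: str = "control",
    background: str = "background",
) -> float:
    """Background-corrected pathology in treated wells relative to controls.

    ``(r_treated - r_background) / (r_control - r_background)`` with
    ``r = psyn_den / map2_area`` per condition: 1 means no effect of the
    treatment, 0 means pathology reduced to the no-seed background level.
    """
    r_treated = q.ratio(treated)
    r_control = q.ratio(control)
    r_background = q.ratio(background)
    denom = r_control - r_background
    if denom <= 0:
        raise ValueError(
            "control ratio must exceed background ratio (nonpositive denominator)"
        )
    return (r_treated - r_background) / denom
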