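"""Synthetic study generators with the statistical structure the pipeline assumes.

These generators stand in for the real study inputs so every pipeline stage
is testable offline: a sparse, directed, heavy-tailed (log-normal weight)
connectome with optional bilateral block structure and weaker contralateral
than ipsilateral projections; regional pathology produced by the forward
spread model itself, spanning several orders of magnitude, corrupted with
multiplicative log-normal observation noise and truncated at a detection
floor (structural zeros); per-gene expression vectors with planted outgoing /
incoming / combined effects for screen validation; and scale-free-ish
regulatory networks with planted hub drivers for enrichment tests.

Every generator is a pure function of its configuration seed, so fixtures are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import networkx as nx
import numpy as np

from .connectome import Connectome, RegionAtlas
from .dynamics import (
    EffectMode,
    GeneExpressionProfile,
    SeedSpec,
    SpreadParameters,
    predict_pathology,
)
from .enrichment import GeneSet, RegulatoryNetwork
from .fitting import PathologyDataset
from .screen import GeneExpressionMatrix

__all__ = [
    "SyntheticConfig",
    "SyntheticGroundTruth",
    "synth_connectome",
    "synth_pathology",
    "synth_gene_matrix",
    "synth_bundle",
    "synth_network_and_sets",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Desk-scale defaults emulating the study conditions.

    40 bilateral regions, two observation times (3 and 6 months post
    injection), a single injected seed region, log-normal projection weights
    whose spread covers roughly three orders of magnitude, multiplicative
    observation noise of 0.3 dex, and a detection floor producing structural
    zeros.  A full-scale profile (410 regions, thousands of genes) is
    reachable by overriding the sizes.
    """

    n_regions: int = 40
    bilateral: bool = True
    density: float = 0.25
    weight_mu: float = 0.0
    # ln-scale spread: +/-2 sigma covers roughly a 1-1000x weight range
    weight_sigma: float = 1.7
    contralateral_attenuation: float = 0.3
    seed_region_count: int = 1
    true_params: SpreadParameters = field(
        default_factory=lambda: SpreadParameters(alpha=0.3, beta=0.5, gamma=0.2, s=0.8)
    )
    noise_sigma: float = 0.3
    detection_floor: float = 1e-4
    times: tuple[float, ...] = (3.0, 6.0)
    n_genes: int = 50
    gene_sigma: float = 0.5
    planted_genes: Mapping[str, EffectMode] = field(default_factory=dict)
    normalize_strength: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.density <= 1.0):
            raise ValueError("density must lie in (0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.detection_floor < 0:
            raise ValueError("detection_floor must be >= 0")
        if self.bilateral and self.n_regions % 2:
            raise ValueError("bilateral atlases need an even region count")


@dataclass
class SyntheticGroundTruth:
    """Everything the generator knew, for parameter-recovery checks."""

    config: SyntheticConfig
    connectome: Connectome
    seed_spec: SeedSpec
    pathology: PathologyDataset
    noiseless: np.ndarray  # exact model output before noise/floor
    true_params: SpreadParameters
    expression: GeneExpressionMatrix | None = None
    planted_datasets: dict[str, tuple[EffectMode, PathologyDataset]] = field(
        default_factory=dict
    )
    generator_connectome: Connectome | None = None  # set when a key subnetwork is planted
    key_edge_indices: np.ndarray | None = None  # flat indices of the planted key edges


def _bilateral_atlas(n: int) -> RegionAtlas:
    half = n // 2
    left = [f"R{i + 1:03d}L" for i in range(half)]
    right = [f"R{i + 1:03d}R" for i in range(half)]
    pairing = {**dict(zip(left, right)), **dict(zip(right, left))}
    return RegionAtlas(tuple(left + right), pairing)


def synth_connectome(config: SyntheticConfig) -> Connectome:
    """Sparse directed connectome with log-normal weight magnitudes.

    With ``bilateral=True`` the atlas is split into mirrored hemispheres and
    the two contralateral blocks are attenuated relative to the ipsilateral
    blocks, so the expected weight structure commutes with the left/right
    swap while individual draws remain independent.
    """
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_regions
    mask = rng.random((n, n)) < config.density
    w = np.where(
        mask, rng.lognormal(config.weight_mu, config.weight_sigma, (n, n)), 0.0
    )
    if config.bilateral:
        half = n // 2
        atten = config.contralateral_attenuation
        w[:half, half:] *= atten
        w[half:, :half] *= atten
        atlas = _bilateral_atlas(n)
    else:
        atlas = RegionAtlas(tuple(f"R{i + 1:03d}" for i in range(n)))
    np.fill_diagonal(w, 0.0)
    if config.normalize_strength and w.max() > 0:
        # unit maximum column strength: diffusion then relaxes on the same
        # timescale as 1/beta, keeping the diffusivity identifiable from
        # observations a few months apart (the usual convention for
        # network-diffusion modelling, where only relative weights matter)
        w = w / w.sum(axis=0).max()
    return Connectome(atlas, w)


def default_seed_spec(connectome: Connectome, config: SyntheticConfig) -> SeedSpec:
    """Deterministic seed choice: the strongest-throughput region(s).

    Mirrors the experimental design of injecting into a highly connected
    deep-gray structure; using total strength makes the choice reproducible
    from the connectome alone.
    """
    strength = connectome.weights.sum(axis=1) + connectome.weights.sum(axis=0)
    order = np.argsort(-strength, kind="stable")
    regions = tuple(
        connectome.atlas.region_ids[i] for i in order[: config.seed_region_count]
    )
    return SeedSpec(regions, config.true_params.gamma)


def synth_pathology(
    connectome: Connectome,
    true_params: SpreadParameters,
    seed_spec: SeedSpec,
    times,
    noise_sigma: float,
    detection_floor: float,
    rng: np.random.Generator,
    gene: GeneExpressionProfile | None = None,
    mode: EffectMode = "global",
    provenance: str = "synthetic",
) -> tuple[PathologyDataset, np.ndarray]:
    """Forward-model pathology with multiplicative log-normal noise.

    ``observed = X_hat(t) * 10**(noise_sigma * Z)`` elementwise, then entries
    below ``detection_floor`` are zeroed (the detection limit of the imaging
    pipeline the data emulate).  Returns the dataset and the exact noiseless
    model output.
    """
    pred = predict_pathology(connectome, true_params, seed_spec, times, gene, mode)
    if not pred.ok:
        raise RuntimeError(f"generator prediction failed: {pred.diagnostic}")
    exact = pred.values
    noisy = exact * 10.0 ** (noise_sigma * rng.standard_normal(exact.shape))
    observed = np.where(noisy < detection_floor, 0.0, noisy)
    data = PathologyDataset(
        atlas=connectome.atlas,
        times=tuple(float(t) for t in times),
        observed=observed,
        provenance=provenance,
    )
    return data, exact


def synth_gene_matrix(
    config: SyntheticConfig,
    connectome: Connectome,
    seed_spec: SeedSpec,
    rng: np.random.Generator,
) -> tuple[GeneExpressionMatrix, dict[str, tuple[EffectMode, PathologyDataset]]]:
    """Decoy genes plus planted-effect genes with their paired datasets.

    Decoys are i.i.d. log-normal across regions.  Each planted gene's vector
    is the one *actually used* to modulate the connectome when generating its
    associated pathology dataset, so a screen over the returned matrix and
    dataset must rank the planted gene first in its effect mode.
    """
    n = connectome.n_regions
    planted = dict(config.planted_genes)
    n_decoys = config.n_genes - len(planted)
    if n_decoys < 0:
        raise ValueError("n_genes smaller than the planted gene count")
    gene_ids = [f"decoy{i + 1:04d}" for i in range(n_decoys)] + list(planted)
    values = rng.lognormal(0.0, config.gene_sigma, (len(gene_ids), n))
    expr = GeneExpressionMatrix(tuple(gene_ids), values, connectome.atlas)
    ledger: dict[str, tuple[EffectMode, PathologyDataset]] = {}
    for gene_id, mode in planted.items():
        profile = expr.profile(gene_id)
        data, _ = synth_pathology(
            connectome,
            config.true_params,
            seed_spec,
            config.times,
            config.noise_sigma,
            config.detection_floor,
            rng,
            gene=profile,
            mode=mode,
            provenance=f"synthetic planted {gene_id} ({mode})",
        )
        ledger[gene_id] = (mode, data)
    return expr, ledger


def synth_bundle(
    config: SyntheticConfig | None = None,
    plant_key_fraction: float | None = None,
    distractor_attenuation: float = 0.05,
) -> SyntheticGroundTruth:
    """End-to-end synthetic study: connectome, seed, pathology, expression.

    With ``plant_key_fraction`` a key subnetwork is planted: the entries of
    the sampled matrix outside the strongest ``plant_key_fraction`` of the
    entry universe are attenuated (they become weak distractors, so the
    planted subnetwork carries nearly all connection weight — the
    concentration real mesoscale connectomes exhibit), and the dynamics are
    generated from the key edges only.  The returned ``connectome`` is the
    full (attenuated) matrix an analyst would observe; the thresholded
    generator matrix and the key edge indices are recorded in the ground
    truth.
    """
    from .perturbation import key_connectome  # local import avoids a cycle

    config = config or SyntheticConfig()
    connectome = synth_connectome(config)
    generator = connectome
    key_idx = None
    if plant_key_fraction is not None:
        key_only, retained = key_connectome(connectome, plant_key_fraction)
        key_mask = key_only.weights.ravel() > 0
        w = connectome.weights.copy()
        w.ravel()[~key_mask] *= distractor_attenuation
        connectome = connectome.with_weights(w)
        generator, _ = key_connectome(connectome, plant_key_fraction)
        key_idx = np.flatnonzero(generator.weights.ravel() > 0)
    seed_spec = default_seed_spec(connectome, config)
    rng = np.random.default_rng(config.rng_seed + 1)
    pathology, exact = synth_pathology(
        generator,
        config.true_params,
        seed_spec,
        config.times,
        config.noise_sigma,
        config.detection_floor,
        rng,
    )
    expression = None
    planted: dict[str, tuple[EffectMode, PathologyDataset]] = {}
    if config.n_genes > 0:
        expression, planted = synth_gene_matrix(config, generator, seed_spec, rng)
    return SyntheticGroundTruth(
        config=config,
        connectome=connectome,
        seed_spec=seed_spec,
        pathology=pathology,
        noiseless=exact,
        true_params=config.true_params,
        expression=expression,
        planted_datasets=planted,
        generator_connectome=None if generator is connectome else generator,
        key_edge_indices=key_idx,
    )


def synth_network_and_sets(
    n_nodes: int,
    n_candidates: int,
    planted_hubs: int,
    rng: np.random.Generator,
    hub_neighborhood: int = 15,
    hub_candidate_fraction: float = 0.8,
) -> tuple[RegulatoryNetwork, GeneSet, list[str]]:
    """Scale-free-ish directed network with optional planted key drivers.

    Planted hubs are wired so their depth-1 neighborhoods are heavily
    over-represented for the candidate set; the ground-truth hub list is
    returned for recovery checks.
    """
    if planted_hubs > n_nodes:
        raise ValueError("more planted hubs than nodes")
    base = nx.scale_free_graph(
        n_nodes, seed=int(rng.integers(0, 2**31 - 1))
    )
    g = nx.DiGraph()
    g.add_nodes_from(range(n_nodes))
    g.add_edges_from((u, v) for u, v in base.edges() if u != v)
    labels = {i: f"g{i + 1:04d}" for i in range(n_nodes)}
    g = nx.relabel_nodes(g, labels)
    node_ids = [labels[i] for i in range(n_nodes)]
    perm = rng.permutation(n_nodes)
    hubs = [node_ids[i] for i in perm[:planted_hubs]]
    candidate_pool = [node_ids[i] for i in perm[planted_hubs:]]
    candidates = sorted(candidate_pool[:n_candidates])
    n_cand_links = int(round(hub_candidate_fraction * hub_neighborhood))
    for hub in hubs:
        chosen = rng.choice(candidates, size=min(n_cand_links, len(candidates)), replace=False)
        fillers = [v for v in candidate_pool[n_candidates:] if v != hub]
        filler_pick = rng.choice(
            fillers, size=min(hub_neighborhood - len(chosen), len(fillers)), replace=False
        )
        for tgt in list(chosen) + list(filler_pick):
            g.add_edge(hub, tgt)
    network = RegulatoryNetwork.from_edges(g.edges())
    return network, GeneSet("candidates", frozenset(candidates)), hubs
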