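"""Plain-text (TSV / JSON) readers and writers for all pipeline inputs and outputs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .connectome import Connectome, RegionAtlas
from .dynamics import PathologyPrediction
from .enrichment import GeneSet, RegulatoryNetwork
from .fitting import FitResult, PathologyDataset
from .screen import GeneExpressionMatrix

__all__ = [
    "write_connectome",
    "write_pathology",
    "read_pathology",
    "write_expression",
    "read_expression",
    "read_gene_set",
    "write_gene_set",
    "read_network",
    "write_network",
    "write_prediction",
    "fit_result_to_dict",
]


def write_connectome(connectome: Connectome, path) -> None:
    """Dense TSV with region labels as first row and first column."""
    ids = list(connectome.atlas.region_ids)
    pd.DataFrame(connectome.weights, index=ids, columns=ids).to_csv(path, sep="\t")


def write_pathology(data: PathologyDataset, path) -> None:
    """Long-format TSV: region, time_months, burden."""
    rows = []
    for t_idx, t in enumerate(data.times):
        for r_idx, region in enumerate(data.atlas.region_ids):
            rows.append(
                {"region": region, "time_months": t, "burden": data.observed[t_idx, r_idx]}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_pathology(path, atlas: RegionAtlas | None = None) -> PathologyDataset:
    df = pd.read_csv(path, sep="\t")
    for col in ("region", "time_months", "burden"):
        if col not in df.columns:
            raise ValueError(f"pathology table is missing column {col!r}")
    df["region"] = df["region"].astype(str)
    if atlas is None:
        seen: list[str] = []
        for r in df["region"]:
            if r not in seen:
                seen.append(r)
        atlas = RegionAtlas(tuple(seen))
    times = tuple(sorted(df["time_months"].unique()))
    obs = np.zeros((len(times), atlas.n_regions))
    for t_idx, t in enumerate(times):
        sub = df[df["time_months"] == t].set_index("region")["burden"]
        missing = set(atlas.region_ids) - set(sub.index)
        if missing:
            raise ValueError(f"missing burdens at t={t} for {sorted(missing)[:5]}")
        obs[t_idx] = sub.loc[list(atlas.region_ids)].to_numpy(dtype=float)
    return PathologyDataset(atlas, times, obs, provenance=str(path))


def write_expression(expr: GeneExpressionMatrix, path, atlas: RegionAtlas) -> None:
    """TSV with genes as rows, regions as columns (header = region labels)."""
    pd.DataFrame(
        expr.values, index=list(expr.gene_ids), columns=list(atlas.region_ids)
    ).to_csv(path, sep="\t")


def read_expression(path, atlas: RegionAtlas | None = None) -> GeneExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if atlas is not None:
        missing = set(atlas.region_ids) - set(map(str, df.columns))
        if missing:
            raise ValueError(f"expression table missing regions {sorted(missing)[:5]}")
        df = df[list(atlas.region_ids)]
    return GeneExpressionMatrix(
        tuple(str(g) for g in df.index), df.to_numpy(dtype=float), atlas
    )


def read_gene_set(path, name: str | None = None) -> GeneSet:
    """One gene id per line; blank lines ignored."""
    members = [
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    ]
    return GeneSet(name or Path(path).stem, frozenset(members))


def write_gene_set(genes: Sequence[str], path) -> None:
    Path(path).write_text("\n".join(genes) + ("\n" if genes else ""))


def read_network(path) -> RegulatoryNetwork:
    """TSV edge list with regulator and target in the first two columns."""
    return RegulatoryNetwork.from_frame(pd.read_csv(path, sep="\t"))


def write_network(network: RegulatoryNetwork, path) -> None:
    pd.DataFrame(network.graph.edges(), columns=["regulator", "target"]).to_csv(
        path, sep="\t", index=False
    )


def write_prediction(
    pred: PathologyPrediction, atlas: RegionAtlas, path
) -> None:
    """Long-format TSV: region, time_months, predicted_burden."""
    rows = []
    for t_idx, t in enumerate(pred.times):
        for r_idx, region in enumerate(atlas.region_ids):
            rows.append(
                {
                    "region": region,
                    "time_months": t,
                    "predicted_burden": pred.values[t_idx, r_idx],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def fit_result_to_dict(fit: FitResult) -> dict:
    """JSON-ready summary of a fit."""
    p = fit.parameters
    return {
        "status": fit.status,
        "parameters": None
        if p is None
        else {"alpha": p.alpha, "beta": p.beta, "gamma": p.gamma, "s": p.s},
        "ccc_per_time": list(fit.ccc_per_time),
        "ave_ccc": fit.ave_ccc,
        "pearson_per_time": list(fit.pearson_per_time),
        "n_regions_used": list(fit.n_regions_used),
        "loss": fit.loss,
    }
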