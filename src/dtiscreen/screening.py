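"""Genome-wide screening and FDR-calibrated network export.

All drug x target combinations are scored by the trained forest to form
a screening matrix.  A probability cutoff is calibrated from pooled
cross-validation predictions at a target false-discovery rate
FDR = FP / (FP + TP); because precision = 1 - FDR at any cutoff, this is
equivalent to reading the cutoff off the precision-recall curve.  Cells
above the cutoff, minus pairs already present in the training set,
become the edges of the predicted bipartite interaction network.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from dtiscreen.classifier import TrainedForest, predict_proba
from dtiscreen.evaluation import CVResult
from dtiscreen.pairs import assemble_features


@dataclass(frozen=True)
class FDRRow:
    """One row of the FDR ladder calibrated from pooled CV predictions."""

    fdr_level: float
    achieved_fdr: float
    recall: float
    threshold: float
    n_predicted: int
    ratio: float
    attainable: bool


def screen_matrix(
    drug_fingerprints: dict[str, np.ndarray],
    protein_vectors: dict[str, np.ndarray],
    model: TrainedForest,
) -> pd.DataFrame:
    """Predict every drug x target combination.

    Returns a dense DataFrame of interaction probabilities with drug
    ids as rows and target ids as columns; cell (i, j) equals the
    one-at-a-time prediction for that pair.
    """
    drug_ids = list(drug_fingerprints)
    target_ids = list(protein_vectors)
    if not drug_ids or not target_ids:
        raise ValueError("need at least one drug and one target")
    rows = []
    for d in drug_ids:
        X = np.stack([
            assemble_features(drug_fingerprints[d], protein_vectors[t])
            for t in target_ids
        ])
        rows.append(predict_proba(model, X))
    return pd.DataFrame(np.array(rows), index=drug_ids, columns=target_ids)


def fdr_calibration(cv: CVResult, fdr_levels) -> list[FDRRow]:
    """Calibrate probability cutoffs to target FDR levels.

    For each level the smallest threshold (over the sorted unique
    pooled-CV scores) whose FDR = FP/(FP+TP) is <= level is chosen,
    maximizing recall; an unattainable level is reported as such rather
    than silently clamped.
    """
    scores = np.asarray(cv.proba, dtype=float)
    labels = np.asarray(cv.labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("FDR calibration requires both classes in the CV result")
    n_pos = int((labels == 1).sum())
    total = len(labels)
    candidates = np.unique(scores)  # ascending
    rows: list[FDRRow] = []
    for level in fdr_levels:
        best = None
        for t in candidates:  # smallest threshold first
            pred = scores >= t
            tp = int((pred & (labels == 1)).sum())
            fp = int((pred & (labels == 0)).sum())
            if tp + fp == 0:
                continue
            fdr = fp / (fp + tp)
            if fdr <= level:
                best = (float(t), fdr, tp, fp)
                break
        if best is None:
            rows.append(FDRRow(level, float("nan"), 0.0, float("nan"), 0, 0.0, False))
            continue
        t, fdr, tp, fp = best
        rows.append(FDRRow(
            fdr_level=level,
            achieved_fdr=fdr,
            recall=tp / n_pos,
            threshold=t,
            n_predicted=tp + fp,
            ratio=(tp + fp) / total,
            attainable=True,
        ))
    return rows


def novel_edges(
    matrix: pd.DataFrame,
    cutoff: float,
    training_pairs: set[tuple[str, str]] | None = None,
    exclude_training: bool = True,
) -> pd.DataFrame:
    """Cells at or above the cutoff as a sorted edge table.

    Training pairs (exact (drug_id, target_id) keys) are excluded when
    ``exclude_training`` is on; otherwise they are kept and flagged via
    the ``is_novel`` column.  Edges are sorted by descending probability
    (ties by drug then target id).
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must be in [0, 1]")
    training_pairs = training_pairs or set()
    records = []
    for d in matrix.index:
        for t in matrix.columns:
            p = float(matrix.at[d, t])
            if p >= cutoff:
                novel = (d, t) not in training_pairs
                if exclude_training and not novel:
                    continue
                records.append((d, t, p, novel))
    edges = pd.DataFrame(records, columns=["drug_id", "target_id", "probability", "is_novel"])
    return edges.sort_values(
        ["probability", "drug_id", "target_id"], ascending=[False, True, True]
    ).reset_index(drop=True)


def to_graph(edges: pd.DataFrame) -> nx.Graph:
    """Bipartite graph with node-type attributes drug/target."""
    g = nx.Graph()
    for _, row in edges.iterrows():
        g.add_node(row["drug_id"], node_type="drug", bipartite=0)
        g.add_node(row["target_id"], node_type="target", bipartite=1)
        g.add_edge(row["drug_id"], row["target_id"], probability=float(row["probability"]))
    return g


def export_network(edges: pd.DataFrame, out_dir: str | Path, prefix: str = "network") -> dict[str, Path]:
    """Write SIF, GraphML, edge CSV and a node-degree summary.

    An empty edge list emits headers only.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sif": out_dir / f"{prefix}.sif",
        "graphml": out_dir / f"{prefix}.graphml",
        "edges": out_dir / f"{prefix}_edges.csv",
        "degrees": out_dir / f"{prefix}_degrees.csv",
    }
    with open(paths["sif"], "w") as fh:
        for _, row in edges.iterrows():
            fh.write(f"{row['drug_id']}\tbinds\t{row['target_id']}\n")
    g = to_graph(edges)
    nx.write_graphml(g, paths["graphml"])
    edges.to_csv(paths["edges"], index=False)
    degrees = pd.DataFrame(
        [(n, g.nodes[n]["node_type"], g.degree[n]) for n in g.nodes],
        columns=["node_id", "node_type", "degree"],
    ).sort_values(["degree", "node_id"], ascending=[False, True])
    degrees.to_csv(paths["degrees"], index=False)
    return paths
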