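"""Labeled drug-target pair dataset assembly.

Replicate Ki measurements for a pair are aggregated by their median,
records from non-human species are removed by a keyword heuristic, pairs
are labeled positive when the median Ki falls strictly below a threshold
(default 10 uM = 10,000 nM; a Ki exactly at the threshold is negative),
and each pair is featurized as a 1191-value vector: the 1024 fingerprint
bits of the drug followed by the 167 protein descriptors of the target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from dtiscreen.fingerprints import N_FINGERPRINT_BITS
from dtiscreen.protein import N_PROTEIN_FEATURES

logger = logging.getLogger(__name__)

N_PAIR_FEATURES = N_FINGERPRINT_BITS + N_PROTEIN_FEATURES  # 1191

DEFAULT_KI_THRESHOLD_NM = 10_000.0  # 10 uM

# Species keywords whose records are excluded to keep pairs human-specific.
DEFAULT_SPECIES_EXCLUDE = (
    "rat", "rabbit", "bovine", "sheep", "calf", "pig",
    "mouse", "guinea pig", "dog", "undefined",
)


@dataclass(frozen=True)
class LabeledPair:
    drug_id: str
    target_id: str
    median_ki_nM: float
    label: int


def aggregate_ki(ki_values_nM) -> float:
    """Median Ki of replicate measurements for one drug-target pair.

    An even number of replicates yields the arithmetic mean of the two
    central values (the standard median).
    """
    values = np.asarray(list(ki_values_nM), dtype=float)
    if values.size == 0:
        raise ValueError("cannot aggregate an empty group of Ki records")
    if (values <= 0).any():
        raise ValueError("Ki values must be positive")
    return float(np.median(values))


def filter_species(
    records: pd.DataFrame,
    exclude: tuple[str, ...] = DEFAULT_SPECIES_EXCLUDE,
) -> pd.DataFrame:
    """Drop records whose species field matches an exclusion keyword.

    Matching is case-insensitive substring search over the free-text
    species column; records with a missing species field are kept.
    Every exclusion is logged.
    """
    if "species" not in records.columns:
        return records
    species = records["species"].fillna("").astype(str).str.lower()
    mask = pd.Series(False, index=records.index)
    for kw in exclude:
        mask |= species.str.contains(kw.lower(), regex=False)
    n_dropped = int(mask.sum())
    if n_dropped:
        for _, row in records.loc[mask].iterrows():
            logger.info(
                "excluding %s-%s (species=%r)",
                row.get("drug_id"), row.get("target_id"), row.get("species"),
            )
    return records.loc[~mask].copy()


def label_pairs(
    records: pd.DataFrame,
    threshold_nM: float = DEFAULT_KI_THRESHOLD_NM,
) -> pd.DataFrame:
    """Aggregate a Ki table to one labeled row per (drug, target) pair.

    ``records`` needs columns drug_id, target_id, ki_nM.  Replicates are
    collapsed to their median and the pair is labeled 1 when median
    Ki < threshold, 0 when median Ki >= threshold.
    """
    if threshold_nM <= 0:
        raise ValueError("Ki threshold must be positive")
    if (records["ki_nM"] <= 0).any():
        bad = records.index[records["ki_nM"] <= 0].tolist()
        raise ValueError(f"non-positive Ki at rows {bad}")
    grouped = (
        records.groupby(["drug_id", "target_id"], sort=True)["ki_nM"]
        .median()
        .reset_index()
        .rename(columns={"ki_nM": "median_ki_nM"})
    )
    grouped["label"] = (grouped["median_ki_nM"] < threshold_nM).astype(int)
    return grouped


def assemble_features(fingerprint: np.ndarray, protein_vector) -> np.ndarray:
    """Concatenate drug fingerprint and protein descriptors (1191 values)."""
    pv = getattr(protein_vector, "values", protein_vector)
    fingerprint = np.asarray(fingerprint, dtype=float)
    pv = np.asarray(pv, dtype=float)
    if fingerprint.shape != (N_FINGERPRINT_BITS,):
        raise ValueError(f"expected {N_FINGERPRINT_BITS} fingerprint bits, got {fingerprint.shape}")
    if pv.shape != (N_PROTEIN_FEATURES,):
        raise ValueError(f"expected {N_PROTEIN_FEATURES} protein descriptors, got {pv.shape}")
    return np.concatenate([fingerprint, pv])


def build_pair_dataset(
    labeled: pd.DataFrame,
    fingerprints: dict[str, np.ndarray],
    protein_vectors: dict[str, np.ndarray],
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Assemble the feature matrix for a labeled pair table.

    Returns ``(X, y, pairs)`` where ``X`` has one 1191-value row per
    pair (drug block first), ``y`` is the 0/1 label vector and ``pairs``
    is the labeled table in matching row order.  Pairs whose drug or
    target lacks a featurization are rejected with the missing ids.
    """
    missing_drugs = sorted(set(labeled["drug_id"]) - set(fingerprints))
    missing_targets = sorted(set(labeled["target_id"]) - set(protein_vectors))
    if missing_drugs or missing_targets:
        raise KeyError(
            f"missing featurizations: drugs {missing_drugs[:5]}, targets {missing_targets[:5]}"
        )
    labeled = labeled.reset_index(drop=True)
    X = np.empty((len(labeled), N_PAIR_FEATURES))
    for i, row in labeled.iterrows():
        X[i] = assemble_features(
            fingerprints[row["drug_id"]], protein_vectors[row["target_id"]]
        )
    y = labeled["label"].to_numpy(dtype=int)
    return X, y, labeled


def pair_feature_names() -> list[str]:
    """Names of the 1191 pair-feature columns."""
    from dtiscreen.protein import protein_feature_names

    return [f"fp.{i}" for i in range(N_FINGERPRINT_BITS)] + protein_feature_names()
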