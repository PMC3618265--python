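"""Synthetic drugs, targets and Ki tables with planted affinity structure.

The generator emulates a curated binding-affinity extract at desk scale:
drugs fall into latent structural classes (each class shares a core
substructure in its SMILES), targets fall into latent families (each
family's sequences are enriched for one hydrophobicity residue group),
and the Ki of a pair is log-normal around a class-x-family mean — tight
binding (low mean log10 Ki) for matched class/family combinations,
weak binding otherwise.  Every pipeline stage (featurization, labeling,
training, screening) is therefore testable without any database
download, with known ground truth.

Two documented presets:

* ``strong_signal_config``: matched-pair mean log10 Ki(nM) = 2,
  mismatched = 5, noise sd = 0.5 — well separated around the 10 uM
  (log10 = 4) labeling threshold.
* ``null_config``: a uniform affinity matrix at log10 Ki = 4, so labels
  are coin flips independent of the features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from dtiscreen.protein import ALPHABETS, STANDARD_AMINO_ACIDS

# residues of each hydrophobicity group, used for family enrichment
_HYDRO_GROUPS = {
    g: [aa for aa in STANDARD_AMINO_ACIDS if ALPHABETS["hydrophobicity"].groups[aa] == g]
    for g in (1, 2, 3)
}

# one core substructure per drug class; ring digits stay clear of the
# decoration alphabet so any concatenation parses
_CLASS_CORES = (
    "c1ccccc1",      # benzene
    "C1CCNCC1",      # piperidine
    "c1ccncc1",      # pyridine
    "C1CCOC1",       # tetrahydrofuran
    "c1ccsc1",       # thiophene
    "C1CCCCC1",      # cyclohexane
)

# decoration fragments; each ends in an atom that accepts a further bond
_DECORATIONS = ("C", "CC", "CCC", "CO", "CN", "CCO", "CCN", "C(C)C", "COC", "CCOC")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic benchmark.

    ``affinity_matrix`` holds the mean log10 Ki (nM) for each
    (drug class, target family) combination; ``noise_sd`` is the sd of
    the log10 Ki noise; ``group_bias`` in [0, 1] is the probability
    that a residue of a family's sequence is drawn from the family's
    enriched hydrophobicity group instead of uniformly.
    """

    n_target_families: int = 4
    targets_per_family: int = 5
    sequence_length_range: tuple[int, int] = (100, 300)
    group_bias: float = 0.5
    n_drug_classes: int = 4
    drugs_per_class: int = 15
    affinity_matrix: tuple[tuple[float, ...], ...] = ()
    noise_sd: float = 0.5
    replicates: int = 1
    species_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_target_families", "targets_per_family", "n_drug_classes",
                     "drugs_per_class", "replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.group_bias <= 1:
            raise ValueError("group_bias must be in [0, 1]")
        lo, hi = self.sequence_length_range
        if lo < 2 or hi < lo:
            raise ValueError("invalid sequence_length_range")
        A = np.asarray(self.affinity_matrix, dtype=float)
        if A.shape != (self.n_drug_classes, self.n_target_families):
            raise ValueError("affinity_matrix shape must be (n_drug_classes, n_target_families)")
        if not np.isfinite(A).all():
            raise ValueError("affinity means must be finite")
        if self.n_drug_classes > len(_CLASS_CORES):
            raise ValueError(f"at most {len(_CLASS_CORES)} drug classes supported")


def matched_affinity_matrix(
    n_classes: int, n_families: int, matched: float = 2.0, mismatched: float = 5.0
) -> tuple[tuple[float, ...], ...]:
    """Diagonal-matched affinity means: class i binds family i tightly."""
    return tuple(
        tuple(matched if c % n_families == f else mismatched for f in range(n_families))
        for c in range(n_classes)
    )


def strong_signal_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """20 targets, 60 drugs, matched log10 Ki 2 vs mismatched 5, sd 0.5."""
    kwargs = dict(
        n_target_families=4, targets_per_family=5,
        n_drug_classes=4, drugs_per_class=15,
        affinity_matrix=matched_affinity_matrix(4, 4, 2.0, 5.0),
        noise_sd=0.5, group_bias=0.5, seed=seed,
    )
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)


def null_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Uniform affinity at the labeling boundary: labels independent of features."""
    kwargs = dict(
        n_target_families=4, targets_per_family=5,
        n_drug_classes=4, drugs_per_class=15,
        affinity_matrix=tuple(tuple(4.0 for _ in range(4)) for _ in range(4)),
        noise_sd=0.5, group_bias=0.5, seed=seed,
    )
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)


@dataclass
class SyntheticBenchmark:
    proteins: pd.DataFrame    # target_id, family, sequence
    drugs: pd.DataFrame       # drug_id, drug_class, smiles
    ki_table: pd.DataFrame    # drug_id, target_id, ki_nM, species, source
    truth: pd.DataFrame       # drug_id, target_id, true_label (noise-free)
    config: GeneratorConfig = field(repr=False)


def generate_proteins(config: GeneratorConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Family-labeled random sequences with hydrophobicity-group enrichment.

    Family f is enriched for hydrophobicity group (f mod 3) + 1: each
    residue is drawn from that group with probability ``group_bias``,
    otherwise uniformly from all 20 amino acids.
    """
    rng = rng or np.random.default_rng(config.seed)
    lo, hi = config.sequence_length_range
    aas = list(STANDARD_AMINO_ACIDS)
    rows = []
    for fam in range(config.n_target_families):
        enriched = _HYDRO_GROUPS[fam % 3 + 1]
        for i in range(config.targets_per_family):
            length = int(rng.integers(lo, hi + 1))
            use_bias = rng.random(length) < config.group_bias
            uniform = rng.choice(aas, size=length)
            biased = rng.choice(enriched, size=length)
            seq = "".join(np.where(use_bias, biased, uniform))
            rows.append((f"T{fam}_{i:03d}", fam, seq))
    return pd.DataFrame(rows, columns=["target_id", "family", "sequence"])


def generate_drugs(config: GeneratorConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Class-labeled SMILES from a fragment grammar: core + decorations.

    Every string is syntactically valid by construction (verified by
    the grammar's composition rules); no chemical realism is claimed.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    rows = []
    seen = set()
    for cls in range(config.n_drug_classes):
        core = _CLASS_CORES[cls]
        for i in range(config.drugs_per_class):
            while True:
                n_dec = int(rng.integers(1, 4))
                decs = [str(rng.choice(_DECORATIONS)) for _ in range(n_dec)]
                smiles = core + "".join(decs)
                if smiles not in seen:
                    seen.add(smiles)
                    break
            rows.append((f"D{cls}_{i:03d}", cls, smiles))
    return pd.DataFrame(rows, columns=["drug_id", "drug_class", "smiles"])


def generate_ki(
    config: GeneratorConfig,
    proteins: pd.DataFrame,
    drugs: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Log-normal Ki for every drug x target pair.

    log10 Ki(nM) = affinity_matrix[class, family] + Normal(0, noise_sd),
    drawn independently per replicate record.  A ``species_fraction``
    of records receives a non-human species string to exercise the
    species filter; the rest are "human".
    """
    for col, frame in (("drug_class", drugs), ("family", proteins)):
        if col not in frame.columns:
            raise ValueError(f"missing {col!r} labels")
    rng = rng or np.random.default_rng(config.seed + 2)
    A = np.asarray(config.affinity_matrix, dtype=float)
    other_species = ("rat", "rabbit", "bovine", "sheep", "calf", "pig",
                     "mouse", "guinea pig", "dog", "undefined")
    rows = []
    for _, drug in drugs.iterrows():
        for _, prot in proteins.iterrows():
            mean = A[int(drug["drug_class"]), int(prot["family"])]
            for _ in range(config.replicates):
                log_ki = mean + rng.normal(0.0, config.noise_sd)
                species = (
                    str(rng.choice(other_species))
                    if rng.random() < config.species_fraction else "human"
                )
                rows.append((drug["drug_id"], prot["target_id"],
                             float(10.0 ** log_ki), species, "synthetic"))
    return pd.DataFrame(rows, columns=["drug_id", "target_id", "ki_nM", "species", "source"])


def make_benchmark(config: GeneratorConfig, threshold_nM: float = 10_000.0) -> SyntheticBenchmark:
    """End-to-end bundle: proteins + drugs + Ki table + noise-free truth."""
    proteins = generate_proteins(config)
    drugs = generate_drugs(config)
    ki = generate_ki(config, proteins, drugs)
    A = np.asarray(config.affinity_matrix, dtype=float)
    truth_rows = [
        (d, t, int(A[int(c), int(f)] < np.log10(threshold_nM)))
        for d, c in zip(drugs["drug_id"], drugs["drug_class"])
        for t, f in zip(proteins["target_id"], proteins["family"])
    ]
    truth = pd.DataFrame(truth_rows, columns=["drug_id", "target_id", "true_label"])
    return SyntheticBenchmark(proteins, drugs, ki, truth, config)


def write_benchmark(bench: SyntheticBenchmark, out_dir: str | Path) -> dict[str, Path]:
    """Write FASTA, .smi, interaction CSV, truth CSV and the config YAML."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out_dir / "targets.fasta",
        "smiles": out_dir / "drugs.smi",
        "interactions": out_dir / "interactions.csv",
        "truth": out_dir / "truth.csv",
        "config": out_dir / "config.yaml",
    }
    with open(paths["fasta"], "w") as fh:
        for _, row in bench.proteins.iterrows():
            fh.write(f">{row['target_id']} family={row['family']}\n")
            seq = row["sequence"]
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    with open(paths["smiles"], "w") as fh:
        for _, row in bench.drugs.iterrows():
            fh.write(f"{row['smiles']} {row['drug_id']}\n")
    bench.ki_table.to_csv(paths["interactions"], index=False)
    bench.truth.to_csv(paths["truth"], index=False)
    cfg = asdict(bench.config)
    cfg["sequence_length_range"] = list(cfg["sequence_length_range"])
    cfg["affinity_matrix"] = [list(r) for r in cfg["affinity_matrix"]]
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return paths
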