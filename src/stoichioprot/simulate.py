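"""Synthetic study generator.

Emulates the statistical structure of an antibody-based pathology-atlas
analysis: a proteome of ~13,000 proteins observed in 12 case samples and
2 single-sample controls, with categorical IHC annotations (4 intensity x
3 fraction levels plus missing), and a planted association between
oxygen-bearing residue usage and expression class.

Per-protein residue composition is drawn from a Dirichlet centred on
human-like amino-acid frequencies; proteins planted as up-regulated get
their oxygen-bearing residue weights (S, T, Y, D, E, N, Q) multiplied by
(1 + delta) before renormalisation, mirroring the premise that selection
acts on the element content of highly expressed proteins.  Expression is
a latent per-condition score in [0, 12], discretised into the categorical
grid through two independently noised copies (one for intensity, one for
stained fraction).  All randomness flows from one seed through a single
numpy Generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ProteinRecord,
    StainingObservation,
    write_expression_table,
    write_fasta,
    write_gmt,
)

#: residues whose side chain carries oxygen
O_BEARING = ("S", "T", "Y", "D", "E", "N", "Q")

#: human-like amino-acid frequencies (fractions; UniProt-scale averages)
HUMAN_AA_FREQS: dict[str, float] = {
    "A": 0.070, "R": 0.056, "N": 0.036, "D": 0.047, "C": 0.023,
    "Q": 0.048, "E": 0.071, "G": 0.066, "H": 0.026, "I": 0.043,
    "L": 0.100, "K": 0.057, "M": 0.021, "F": 0.037, "P": 0.063,
    "S": 0.083, "T": 0.053, "W": 0.012, "Y": 0.027, "V": 0.060,
}

#: rough relative gene counts per chromosome (karyotype order)
_CHROM_WEIGHTS: dict[str, float] = {
    "1": 2000, "2": 1300, "3": 1100, "4": 800, "5": 900, "6": 1000,
    "7": 900, "8": 700, "9": 800, "10": 700, "11": 1300, "12": 1000,
    "13": 300, "14": 600, "15": 600, "16": 800, "17": 1200, "18": 300,
    "19": 1400, "20": 500, "21": 200, "22": 400, "X": 800, "Y": 50, "MT": 13,
}

# latent-score bin edges for the categorical grid
_INTENSITY_EDGES = (1.5, 4.5, 9.0)  # negative | weak | moderate | strong
_FRACTION_EDGES = (4.0, 9.0)  # <25% | 25-75% | >75%
_INTENSITY_LABELS = ("negative", "weak", "moderate", "strong")
_FRACTION_LABELS = ("<25%", "25-75%", ">75%")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters of the synthetic atlas.

    Defaults are the emulated study's conditions: 13,000 proteins scored
    in 12 case samples against 2 single-sample controls, ~2% planted
    up-regulated and ~6% down-regulated proteins, and 5% missing
    annotations.  The default oxygen tilt delta = 0.05 raises the expected
    [O] of up-class proteins by ~3% relative to the rest — the magnitude
    of the up-vs-down oxygen difference the generator emulates; a
    (1+delta) tilt on oxygen-bearing weights changes [O] by the factor
    (1+delta)/(1+q*delta) with q ~ 0.37 the mass fraction of oxygen-
    bearing residues.
    """

    n_proteins: int = 13000
    n_case_samples: int = 12
    n_control_samples: int = 2
    length_range: tuple[int, int] = (100, 1000)
    base_composition: dict[str, float] = field(
        default_factory=lambda: dict(HUMAN_AA_FREQS)
    )
    dirichlet_concentration: float = 200.0
    oxygen_effect: float = 0.05
    frac_up: float = 0.02
    frac_down: float = 0.06
    missing_rate: float = 0.05
    noise_sd: float = 1.5
    high_expression_threshold: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.oxygen_effect <= -1:
            raise ValueError("oxygen_effect must be > -1")
        for name in ("frac_up", "frac_down", "missing_rate"):
            val = getattr(self, name)
            if not 0 <= val <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {val}")
        if self.frac_up + self.frac_down > 1:
            raise ValueError("frac_up + frac_down must not exceed 1")
        if any(w <= 0 for w in self.base_composition.values()):
            raise ValueError("composition weights must be positive")
        if self.length_range[0] < 1 or self.length_range[1] < self.length_range[0]:
            raise ValueError("invalid length_range")


def _rng(config: SyntheticConfig) -> np.random.Generator:
    return np.random.default_rng(config.seed)


def generate_proteome(
    config: SyntheticConfig,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Generate protein records and the ground-truth table.

    The truth table records each protein's planted class (up/down/null),
    baseline expression latent, gene symbol, chromosome and expected
    oxygen content under its tilted composition.  The oxygen tilt is
    applied to up-class proteins and to null proteins whose baseline
    latent exceeds ``high_expression_threshold`` (flagged ``high``), so
    the association between oxygen usage and expression level holds in
    case and control conditions alike, not only among regulated proteins.
    Up/down-class proteins are never placed on Y (the emulated finding
    that DEP genes avoid the Y chromosome); Y-linked genes occur only
    among null proteins.
    """
    rng = _rng(config)
    n = config.n_proteins
    residues = sorted(config.base_composition)
    freqs = np.array([config.base_composition[r] for r in residues])
    freqs = freqs / freqs.sum()
    o_mask = np.array([r in O_BEARING for r in residues])
    # side-chain O atoms per residue, aligned with `residues`
    from .elements import ElementCompositionTable

    table = ElementCompositionTable.default()
    w_o = np.array([table.count(r, "O") for r in residues], dtype=float)

    n_up = math.ceil(config.frac_up * n)
    n_down = math.ceil(config.frac_down * n)
    classes = np.array(["null"] * n, dtype=object)
    order = rng.permutation(n)
    classes[order[:n_up]] = "up"
    classes[order[n_up : n_up + n_down]] = "down"

    # one latent baseline per protein; null proteins share it across
    # conditions, and high-baseline nulls carry the oxygen tilt too
    baseline = rng.uniform(1.0, 11.0, size=n)
    high = (classes == "null") & (baseline >= config.high_expression_threshold)
    tilted = (classes == "up") | high

    chroms = list(_CHROM_WEIGHTS)
    cw = np.array([_CHROM_WEIGHTS[c] for c in chroms], dtype=float)
    cw /= cw.sum()
    no_y = np.array([c != "Y" for c in chroms])
    cw_no_y = cw * no_y
    cw_no_y /= cw_no_y.sum()

    lengths = rng.integers(config.length_range[0], config.length_range[1] + 1, size=n)

    records: list[ProteinRecord] = []
    truth_rows = []
    width = len(str(n))
    for i in range(n):
        mean = freqs.copy()
        if tilted[i] and config.oxygen_effect != 0:
            mean = mean * np.where(o_mask, 1.0 + config.oxygen_effect, 1.0)
            mean /= mean.sum()
        alpha = mean * config.dirichlet_concentration
        comp = rng.dirichlet(alpha)
        counts = rng.multinomial(lengths[i], comp)
        seq_arr = np.repeat(np.frombuffer("".join(residues).encode(), np.uint8), counts)
        rng.shuffle(seq_arr)
        seq = seq_arr.tobytes().decode("ascii")
        pid = f"P{i:0{width}d}"
        gene = f"GENE{i:0{width}d}"
        weights = cw_no_y if classes[i] in ("up", "down") else cw
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        records.append(
            ProteinRecord(protein_id=pid, gene_symbol=gene, chromosome=chrom, sequence=seq)
        )
        truth_rows.append(
            {
                "protein_id": pid,
                "gene_symbol": gene,
                "chromosome": chrom,
                "planted_class": classes[i],
                "high_expression": bool(high[i]),
                "baseline_expression": float(baseline[i]),
                "length": int(lengths[i]),
                "expected_O": float(np.dot(w_o, comp)),
            }
        )
    truth = pd.DataFrame(truth_rows).set_index("protein_id")
    return records, truth


def _discretize(x: np.ndarray, edges: tuple[float, ...]) -> np.ndarray:
    return np.digitize(x, edges)


def generate_expression(
    config: SyntheticConfig, truth: pd.DataFrame
) -> list[StainingObservation]:
    """Generate categorical IHC observations from the planted classes.

    Latent per-condition score: null proteins use the truth table's
    baseline (drawn from U(1, 11)) in both conditions; up proteins have
    case ~ U(9, 12) and control ~ U(0, 1.5); down proteins the mirror
    image.  Each sample
    draws two independently noised copies of the latent score (sd =
    ``noise_sd``, clipped to [0, 12]); one is binned into intensity, the
    other into stained fraction.  Missing markers are injected at
    ``missing_rate`` per protein x sample.
    """
    rng = np.random.default_rng(config.seed + 1)
    classes = truth["planted_class"].to_numpy()
    base = truth["baseline_expression"].to_numpy(dtype=float)
    case_mu = base.copy()
    ctrl_mu = base.copy()
    up = classes == "up"
    down = classes == "down"
    case_mu[up] = rng.uniform(9.0, 12.0, size=int(up.sum()))
    ctrl_mu[up] = rng.uniform(0.0, 1.5, size=int(up.sum()))
    case_mu[down] = rng.uniform(0.0, 1.5, size=int(down.sum()))
    ctrl_mu[down] = rng.uniform(9.0, 12.0, size=int(down.sum()))

    sample_ids = [f"case_{i+1:02d}" for i in range(config.n_case_samples)] + [
        f"control_{i+1:02d}" for i in range(config.n_control_samples)
    ]
    mus = np.column_stack(
        [case_mu] * config.n_case_samples + [ctrl_mu] * config.n_control_samples
    )
    noise_i = rng.normal(0.0, config.noise_sd, size=mus.shape) if config.noise_sd else 0.0
    noise_f = rng.normal(0.0, config.noise_sd, size=mus.shape) if config.noise_sd else 0.0
    x_i = np.clip(mus + noise_i, 0.0, 12.0)
    x_f = np.clip(mus + noise_f, 0.0, 12.0)
    int_idx = _discretize(x_i, _INTENSITY_EDGES)
    frac_idx = _discretize(x_f, _FRACTION_EDGES)
    missing = rng.random(size=mus.shape) < config.missing_rate

    observations: list[StainingObservation] = []
    pids = list(truth.index)
    for j, sid in enumerate(sample_ids):
        for i, pid in enumerate(pids):
            if missing[i, j]:
                observations.append(StainingObservation(pid, sid, None, None))
            else:
                observations.append(
                    StainingObservation(
                        pid,
                        sid,
                        _INTENSITY_LABELS[int_idx[i, j]],
                        _FRACTION_LABELS[frac_idx[i, j]],
                    )
                )
    return observations


def generate_gene_sets(
    config: SyntheticConfig,
    truth: pd.DataFrame,
    n_sets: int = 20,
    size_range: tuple[int, int] = (30, 80),
) -> dict[str, set[str]]:
    """Random gene sets plus two planted sets enriched in up/down genes."""
    rng = np.random.default_rng(config.seed + 2)
    genes = truth["gene_symbol"].to_numpy()
    classes = truth["planted_class"].to_numpy()
    sets: dict[str, set[str]] = {}
    for i in range(n_sets):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        size = min(size, len(genes))
        members = rng.choice(genes, size=size, replace=False)
        sets[f"RANDOM_SET_{i+1:02d}"] = set(members)
    for direction in ("up", "down"):
        pool = genes[classes == direction]
        other = genes[classes != direction]
        if len(pool) == 0:
            continue
        k_dir = min(len(pool), 40)
        k_other = min(len(other), 20)
        members = set(rng.choice(pool, size=k_dir, replace=False)) | set(
            rng.choice(other, size=k_other, replace=False)
        )
        sets[f"PLANTED_{direction.upper()}_SET"] = members
    return sets


@dataclass
class SyntheticStudy:
    """In-memory bundle of one synthetic study."""

    config: SyntheticConfig
    records: list[ProteinRecord]
    truth: pd.DataFrame
    observations: list[StainingObservation]
    annotation: dict[str, str]
    gene_sets: dict[str, set[str]]
    case_samples: list[str]
    control_samples: list[str]


def generate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Generate the full study (proteome, expression, annotation, sets)."""
    records, truth = generate_proteome(config)
    observations = generate_expression(config, truth)
    annotation = {
        row.gene_symbol.upper(): row.chromosome for row in truth.itertuples()
    }
    gene_sets = generate_gene_sets(config, truth)
    case = [f"case_{i+1:02d}" for i in range(config.n_case_samples)]
    ctrl = [f"control_{i+1:02d}" for i in range(config.n_control_samples)]
    return SyntheticStudy(
        config=config,
        records=records,
        truth=truth,
        observations=observations,
        annotation=annotation,
        gene_sets=gene_sets,
        case_samples=case,
        control_samples=ctrl,
    )


def write_bundle(config: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the study to disk in the formats the pipeline reads.

    Emits proteome.fasta, expression.tsv, annotation.tsv, gene_sets.gmt
    and truth.tsv; byte-identical for identical configs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = generate_study(config)
    paths = {
        "fasta": outdir / "proteome.fasta",
        "expression": outdir / "expression.tsv",
        "annotation": outdir / "annotation.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(paths["fasta"], study.records)
    write_expression_table(paths["expression"], study.observations)
    with open(paths["annotation"], "w", encoding="utf-8") as fh:
        fh.write("gene\tchromosome\n")
        for gene in sorted(study.annotation):
            fh.write(f"{gene}\t{study.annotation[gene]}\n")
    write_gmt(paths["gene_sets"], {k: study.gene_sets[k] for k in sorted(study.gene_sets)})
    study.truth.sort_index().to_csv(paths["truth"], sep="\t")
    return paths


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    return replace(config, seed=seed)
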