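"""Synthetic small-RNA data generator with a ground-truth manifest.

Produces hairpins with annotated arms, per-sample FASTQ reads drawn from the
arms, lncRNAs carrying planted miRNA-complementary sites, and count matrices
with planted antagonistic differential expression — the verifiable test
substrate for the rest of the pipeline.

Negative binomial counts are parameterized by (mean m, dispersion alpha)
with variance m + alpha * m**2; alpha = 0 degenerates to Poisson.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .arm_analysis import ArmCountTable, Condition
from .interaction import DuplexParams, reverse_complement, score_duplex
from .io_formats import (
    CountMatrix,
    HairpinLocus,
    SampleRecord,
    write_count_matrix,
    write_fasta_sequences,
    write_hairpin_annotation,
    write_sample_sheet,
)
from .read_processing import FastqRead

RNA_BASES = np.array(list("ACGU"))
READ_QUALITY_CHAR = chr(35 + 33)  # constant Phred 35


@dataclass(frozen=True)
class SimConfig:
    n_hairpins: int = 20
    n_switch_loci: int = 4
    arm_prop_a: float = 0.9   # true 5p proportion in switch tissue A
    arm_prop_b: float = 0.1   # and in tissue B
    nb_mean: float = 400.0
    nb_dispersion: float = 0.05
    n_replicates: int = 3
    accessions: tuple[str, ...] = ("C08", "W05")
    tissues: tuple[str, ...] = ("root", "leaf")
    time_points_h: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 24.0, 48.0)
    n_lncrnas: int = 10
    n_interacting_pairs: int = 3
    planted_lfc: float = 2.0
    seq_error_rate: float = 0.0
    adapter3p: str = "UCGUAUGCCGUCUUCUGCUUG"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_switch_loci > self.n_hairpins:
            raise ValueError("n_switch_loci must be <= n_hairpins")
        if self.n_interacting_pairs > self.n_lncrnas:
            raise ValueError("n_interacting_pairs must be <= n_lncrnas")
        for prop in (self.arm_prop_a, self.arm_prop_b):
            if not (0.0 < prop < 1.0):
                raise ValueError("arm proportions must lie in (0, 1)")
        if not (0.0 <= self.seq_error_rate < 1.0):
            raise ValueError("seq_error_rate must lie in [0, 1)")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")

    @property
    def conditions(self) -> list[Condition]:
        return [
            (acc, tis, t)
            for acc in self.accessions
            for tis in self.tissues
            for t in self.time_points_h
        ]


@dataclass
class TruthManifest:
    switch_loci: list[dict] = field(default_factory=list)
    de_features: list[dict] = field(default_factory=list)
    interacting_pairs: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(RNA_BASES, size=length))


def dinucleotide_shuffle(seq: str, rng: np.random.Generator,
                         max_tries: int = 500) -> str:
    """Shuffle preserving dinucleotide counts (random Eulerian walk on the
    transition multigraph, retried until all edges are consumed)."""
    if len(seq) < 3:
        return seq
    for _ in range(max_tries):
        edges: dict[str, list[str]] = {}
        for a, b in zip(seq, seq[1:]):
            edges.setdefault(a, []).append(b)
        for k in edges:
            order = rng.permutation(len(edges[k]))
            edges[k] = [edges[k][i] for i in order]
        out = [seq[0]]
        node = seq[0]
        n_edges = len(seq) - 1
        for _step in range(n_edges):
            stack = edges.get(node)
            if not stack:
                break
            node = stack.pop()
            out.append(node)
        if len(out) == len(seq):
            return "".join(out)
    return seq  # give up; original still preserves dinucleotide counts


def nb_sample(rng: np.random.Generator, mean: float, dispersion: float,
              size=None) -> np.ndarray | int:
    """NB(mean, alpha) with variance mean + alpha*mean^2; alpha=0 -> Poisson."""
    if mean < 0:
        raise ValueError("mean must be >= 0")
    if mean == 0:
        return np.zeros(size, dtype=np.int64) if size else 0
    if dispersion == 0:
        return rng.poisson(mean, size=size)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


# ---------------------------------------------------------------------------
# Hairpins
# ---------------------------------------------------------------------------

def generate_hairpins(cfg: SimConfig, rng: np.random.Generator) -> list[HairpinLocus]:
    """Random 21-nt 5p arm + 12-18 nt loop + mutated reverse complement 3p arm."""
    loci: list[HairpinLocus] = []
    for i in range(cfg.n_hairpins):
        hid = f"hp{i:04d}"
        arm5 = _random_seq(rng, 21)
        loop = _random_seq(rng, int(rng.integers(12, 19)))
        arm3 = list(reverse_complement(arm5))
        for pos in rng.choice(len(arm3), size=2, replace=False):
            current = arm3[pos]
            choices = [b for b in "ACGU" if b != current]
            arm3[pos] = choices[int(rng.integers(0, 3))]
        seq = arm5 + loop + "".join(arm3)
        loci.append(
            HairpinLocus(
                hairpin_id=hid,
                sequence=seq,
                arm5p=(0, 21),
                arm3p=(21 + len(loop), len(seq)),
                mature5p_id=f"{hid}-5p",
                mature3p_id=f"{hid}-3p",
            )
        )
    return loci


def make_design(cfg: SimConfig) -> list[SampleRecord]:
    records = []
    for acc in cfg.accessions:
        for tis in cfg.tissues:
            for t in cfg.time_points_h:
                for rep in range(1, cfg.n_replicates + 1):
                    sid = f"{acc}_{tis}_{t:g}h_r{rep}"
                    records.append(
                        SampleRecord(
                            sample_id=sid, accession=acc, tissue=tis,
                            time_h=t, replicate=rep,
                            fastq_path=f"reads/{sid}.fastq",
                        )
                    )
    return records


def switch_truth(cfg: SimConfig, loci: Sequence[HairpinLocus]) -> dict[str, dict]:
    """Planted true 5p proportion per hairpin per tissue.

    The first ``n_switch_loci`` hairpins carry ``arm_prop_a`` in the first
    tissue and ``arm_prop_b`` in the second; all other loci sit at 0.5
    everywhere.
    """
    truth: dict[str, dict] = {}
    tis_a, tis_b = cfg.tissues[0], cfg.tissues[1] if len(cfg.tissues) > 1 else cfg.tissues[0]
    for i, locus in enumerate(loci):
        if i < cfg.n_switch_loci:
            props = {tis: 0.5 for tis in cfg.tissues}
            props[tis_a] = cfg.arm_prop_a
            props[tis_b] = cfg.arm_prop_b
            truth[locus.hairpin_id] = {"switch": True, "props": props}
        else:
            truth[locus.hairpin_id] = {
                "switch": False, "props": {tis: 0.5 for tis in cfg.tissues}
            }
    return truth


def simulate_arm_counts(
    cfg: SimConfig,
    loci: Sequence[HairpinLocus],
    samples: Sequence[SampleRecord],
    rng: np.random.Generator,
) -> ArmCountTable:
    """True per-sample arm counts: NB totals split binomially by the planted
    5p proportion of the sample's tissue."""
    truth = switch_truth(cfg, loci)
    table = ArmCountTable([h.hairpin_id for h in loci], [s.sample_id for s in samples])
    for locus in loci:
        props = truth[locus.hairpin_id]["props"]
        for s in samples:
            total = int(nb_sample(rng, cfg.nb_mean, cfg.nb_dispersion))
            c5 = int(rng.binomial(total, props[s.tissue])) if total else 0
            table.set(locus.hairpin_id, s.sample_id, c5, total - c5)
    return table


def _mutate_bases(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            choices = [b for b in "ACGU" if b != chars[i]]
            chars[i] = choices[int(rng.integers(0, 3))]
    return "".join(chars)


def simulate_arm_reads(
    cfg: SimConfig,
    loci: Sequence[HairpinLocus],
    samples: Sequence[SampleRecord],
    rng: np.random.Generator,
) -> tuple[dict[str, list[FastqRead]], ArmCountTable]:
    """FASTQ reads per sample plus the true arm-count table.

    Reads are exact arm sequences (optionally mutated at ``seq_error_rate``)
    with the 3' adapter appended and constant Phred-35 qualities.
    """
    counts = simulate_arm_counts(cfg, loci, samples, rng)
    reads: dict[str, list[FastqRead]] = {s.sample_id: [] for s in samples}
    for locus in loci:
        for s in samples:
            row = counts.get(locus.hairpin_id, s.sample_id)
            for arm_seq, n, tag in (
                (locus.seq5p, row.count5p, "5p"),
                (locus.seq3p, row.count3p, "3p"),
            ):
                for k in range(n):
                    seq = _mutate_bases(arm_seq, rng, cfg.seq_error_rate)
                    full = seq + cfg.adapter3p
                    rid = f"{locus.hairpin_id}_{tag}_{s.sample_id}_{k}"
                    reads[s.sample_id].append(
                        FastqRead(rid, full, READ_QUALITY_CHAR * len(full))
                    )
    return reads, counts


# ---------------------------------------------------------------------------
# lncRNAs with planted complementary sites
# ---------------------------------------------------------------------------

def _plant_wobble(site: str, mirna: str, params: DuplexParams,
                  rng: np.random.Generator) -> str | None:
    """Mutate one non-seed target base of a perfect-complement site to a G:U
    wobble; returns None when no eligible position exists."""
    n = len(mirna)
    eligible = [
        i for i in range(1, n + 1)
        if not params.in_seed(i) and mirna[i - 1] in ("G", "U")
    ]
    if not eligible:
        return None
    pos = int(rng.choice(eligible))
    # miRNA position pos pairs with site index n - pos (antiparallel)
    idx = n - pos
    chars = list(site)
    chars[idx] = "U" if mirna[pos - 1] == "G" else "G"
    return "".join(chars)


def generate_lncrnas_with_sites(
    cfg: SimConfig,
    mirna_sequences: dict[str, str],
    rng: np.random.Generator,
    planted_penalty: float = 0.0,
    duplex_params: DuplexParams = DuplexParams(),
) -> tuple[dict[str, str], list[dict]]:
    """Random 400-800 nt lncRNAs; the first ``n_interacting_pairs`` carry a
    planted complementarity site for a miRNA chosen round-robin.

    ``planted_penalty`` 0 plants an exact reverse complement; a positive value
    (== wobble penalty) plants a single non-seed G:U wobble.
    """
    mirna_ids = list(mirna_sequences)
    lncrnas: dict[str, str] = {}
    planted: list[dict] = []
    for i in range(cfg.n_lncrnas):
        lid = f"lnc{i:04d}"
        length = int(rng.integers(400, 801))
        seq = _random_seq(rng, length)
        if i < cfg.n_interacting_pairs and mirna_ids:
            mid = mirna_ids[i % len(mirna_ids)]
            mseq = mirna_sequences[mid]
            site = reverse_complement(mseq)
            penalty = 0.0
            if planted_penalty > 0:
                mutated = _plant_wobble(site, mseq, duplex_params, rng)
                if mutated is not None:
                    site = mutated
                    penalty = duplex_params.wobble_penalty
            pos = int(rng.integers(30, length - len(site) - 30))
            seq = seq[:pos] + site + seq[pos + len(site):]
            planted.append(
                {
                    "mirna_id": mid,
                    "lncrna_id": lid,
                    "site_interval": [pos, pos + len(site)],
                    "planted_penalty": penalty,
                }
            )
        lncrnas[lid] = seq
    return lncrnas, planted


# ---------------------------------------------------------------------------
# Expression matrices with planted antagonistic DE
# ---------------------------------------------------------------------------

def simulate_expression(
    cfg: SimConfig,
    samples: Sequence[SampleRecord],
    mirna_ids: Sequence[str],
    lncrna_ids: Sequence[str],
    planted_pairs: Sequence[dict],
    rng: np.random.Generator,
    contrast: tuple[Condition, Condition] | None = None,
) -> tuple[CountMatrix, CountMatrix, list[dict]]:
    """NB count matrices for miRNAs and lncRNAs with planted antagonism.

    For each planted pair, in condition B of the chosen contrast the miRNA
    mean is multiplied by 2**(-planted_lfc) and the lncRNA mean by
    2**(+planted_lfc) (miRNA down, lncRNA up). Returns the two matrices plus
    DE truth entries.
    """
    conds = cfg.conditions
    if contrast is None:
        acc, tis = cfg.accessions[0], cfg.tissues[0]
        contrast = ((acc, tis, cfg.time_points_h[0]),
                    (acc, tis, cfg.time_points_h[-1]))
    cond_a, cond_b = contrast

    mirna_in_pair = {p["mirna_id"] for p in planted_pairs}
    lncrna_in_pair = {p["lncrna_id"] for p in planted_pairs}

    def make_matrix(feature_ids: Sequence[str], down_set: set[str],
                    up_set: set[str]) -> CountMatrix:
        counts = np.zeros((len(feature_ids), len(samples)), dtype=np.int64)
        for i, fid in enumerate(feature_ids):
            for j, s in enumerate(samples):
                mean = cfg.nb_mean
                if s.condition == cond_b:
                    if fid in down_set:
                        mean *= 2.0 ** (-cfg.planted_lfc)
                    elif fid in up_set:
                        mean *= 2.0 ** (cfg.planted_lfc)
                counts[i, j] = int(nb_sample(rng, mean, cfg.nb_dispersion))
        # library size = total retained reads, dominated by reads outside the
        # matrix; held constant so CPM tracks the true per-feature means
        libsize = max(int(cfg.nb_mean * max(len(feature_ids), 1) * 10), 1)
        libsizes = np.full(len(samples), libsize, dtype=np.int64)
        return CountMatrix(list(feature_ids), [s.sample_id for s in samples],
                           counts, libsizes)

    mirna_mat = make_matrix(mirna_ids, mirna_in_pair, set())
    lncrna_mat = make_matrix(lncrna_ids, set(), lncrna_in_pair)

    label = {"a": list(cond_a), "b": list(cond_b)}
    de_truth = []
    for p in planted_pairs:
        de_truth.append({"feature_id": p["mirna_id"], "contrast": label,
                         "direction": "down", "true_lfc": -cfg.planted_lfc})
        de_truth.append({"feature_id": p["lncrna_id"], "contrast": label,
                         "direction": "up", "true_lfc": cfg.planted_lfc})
    return mirna_mat, lncrna_mat, de_truth


# ---------------------------------------------------------------------------
# Full dataset emission
# ---------------------------------------------------------------------------

def generate_dataset(cfg: SimConfig, out_dir: str | Path) -> TruthManifest:
    """Emit every artifact (FASTA, GFF3, FASTQ, TSVs, truth.json) to out_dir."""
    out = Path(out_dir)
    (out / "reads").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    loci = generate_hairpins(cfg, rng)
    write_hairpin_annotation(loci, out / "hairpins.fa", out / "arms.gff3")

    samples = make_design(cfg)
    write_sample_sheet(samples, out / "samples.tsv")

    reads, true_counts = simulate_arm_reads(cfg, loci, samples, rng)
    from .read_processing import write_fastq
    for s in samples:
        write_fastq(reads[s.sample_id], out / "reads" / f"{s.sample_id}.fastq")
    true_counts.to_tsv(out / "true_arm_counts.tsv")

    matures = {
        arm_id: seq
        for locus in loci
        for arm_id, seq in ((locus.mature5p_id, locus.seq5p),
                            (locus.mature3p_id, locus.seq3p))
    }
    write_fasta_sequences(matures, out / "matures.fa")

    lncrnas, planted_sites = generate_lncrnas_with_sites(cfg, matures, rng)
    write_fasta_sequences(lncrnas, out / "lncrna.fa")

    mirna_mat, lncrna_mat, de_truth = simulate_expression(
        cfg, samples, list(matures), list(lncrnas), planted_sites, rng
    )
    write_count_matrix(mirna_mat, out / "counts_mirna.tsv")
    write_count_matrix(lncrna_mat, out / "abund_lncrna.tsv")

    truth_props = switch_truth(cfg, loci)
    manifest = TruthManifest(interacting_pairs=planted_sites, de_features=de_truth)
    tis_a = cfg.tissues[0]
    tis_b = cfg.tissues[1] if len(cfg.tissues) > 1 else cfg.tissues[0]
    for locus in loci:
        if truth_props[locus.hairpin_id]["switch"]:
            for acc in cfg.accessions:
                for t in cfg.time_points_h:
                    manifest.switch_loci.append(
                        {
                            "hairpin_id": locus.hairpin_id,
                            "condition_a": [acc, tis_a, t],
                            "condition_b": [acc, tis_b, t],
                            "dominance_a": "dominant5p" if cfg.arm_prop_a > 0.5
                                           else "dominant3p",
                            "dominance_b": "dominant5p" if cfg.arm_prop_b > 0.5
                                           else "dominant3p",
                        }
                    )
    manifest.to_json(out / "truth.json")
    return manifest
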