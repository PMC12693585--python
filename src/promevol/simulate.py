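"""Synthetic data with known truth for every pipeline stage.

The generator emulates the statistical structure of the real inputs — a
tissue expression atlas, CAGE tracks with dominant peaks at annotated
TSSs, reference-anchored multi-species promoter alignments accumulating
substitutions and indels (optionally with an elevated-rate hotspot
window), per-base conservation tracks depressed where events occurred,
negative-binomial count matrices with per-gene fold changes, and hybrid
allele-count tables under cis-maintained or one-allele-dominant
regulation. Events are generated directly on the reference coordinate
frame and alignments emitted with explicit gaps, so the recorded truth is
an exact oracle for the event-coding stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .events import PromoterAlignment
from .genomic import GenomicInterval, SignalTrack

BASES = np.array(list("ACGT"))

#: divergence scalars for the four non-reference species, a ladder echoing
#: increasing distance from the reference within a closely related subgroup
DEFAULT_SPECIES = {
    "species_sim": 0.4,
    "species_sec": 0.5,
    "species_yak": 1.0,
    "species_ere": 1.2,
}


@dataclass
class AlignmentConfig:
    upstream: int = 1000
    downstream: int = 300
    sub_rate: float = 0.05  # per-site substitution probability at scalar 1
    indel_rate: float = 0.01  # per-site indel-start probability (split ins/del)
    indel_mean_len: float = 3.0  # geometric length distribution
    hotspot_region: tuple[int, int] | None = (-380, -31)  # inclusive offsets
    hotspot_multiplier: float = 4.0
    species: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SPECIES))

    @property
    def length(self) -> int:
        return self.upstream + self.downstream


@dataclass
class CageConfig:
    track_length: int = 1300
    n_candidates: int = 4
    peak_height: tuple[float, float] = (20.0, 60.0)
    dominance: float = 5.0  # scale factor of the dominant peak
    peak_halfwidth: int = 2


@dataclass
class ConservationConfig:
    background_mean: float = 1.0
    background_sd: float = 0.5
    depression: float = 1.5  # subtracted at event positions


@dataclass
class ExpressionConfig:
    n_genes: int = 300
    n_replicates: int = 3
    nb_mean: float = 200.0
    nb_dispersion: float = 0.1
    log2fc_sd: float = 1.0
    hybrid_scenario: str = "cis_maintained"  # or dominant_A / dominant_B
    dominance_log2: float = 2.0
    x_fraction: float = 0.15
    length_range: tuple[int, int] = (500, 3000)


@dataclass
class TissueConfig:
    n_specific: int = 20
    n_uniform: int = 80
    n_tissues: int = 10
    specific_level: float = 100.0
    leakage: float = 0.05  # max off-tissue fraction of the specific level
    uniform_level: float = 50.0
    uniform_noise: float = 0.1


@dataclass
class SimConfig:
    seed: int = 0
    n_genes: int = 20
    alignment: AlignmentConfig = field(default_factory=AlignmentConfig)
    cage: CageConfig = field(default_factory=CageConfig)
    conservation: ConservationConfig = field(default_factory=ConservationConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    tissue: TissueConfig = field(default_factory=TissueConfig)


def _geometric_len(rng: np.random.Generator, mean: float) -> int:
    return int(rng.geometric(min(1.0, 1.0 / mean)))


def simulate_promoter_alignment(
    cfg: AlignmentConfig, gene: str, rng: np.random.Generator
) -> tuple[PromoterAlignment, list[dict]]:
    """One reference-anchored multi-species alignment plus its truth events.

    The reference sequence covers offsets [-upstream, +downstream); each
    non-reference species is derived by per-site substitutions and
    geometric-length indels at divergence-scaled rates, multiplied inside
    the hotspot window. Truth records, per species, every collapsed event
    with its 5'-start offset, kind and length.
    """
    L = cfg.length
    ref = rng.choice(BASES, size=L)
    offsets = np.arange(L) - cfg.upstream

    def rate_scale(offset: int) -> float:
        if cfg.hotspot_region is None:
            return 1.0
        lo, hi = cfg.hotspot_region
        return cfg.hotspot_multiplier if lo <= offset <= hi else 1.0

    truth: list[dict] = []
    species_rows: dict[str, dict] = {}
    for sp, scalar in cfg.species.items():
        deleted = np.zeros(L, dtype=bool)
        subbed = {}  # position -> substituted base
        inserts = {}  # junction position (after this ref index) -> inserted string
        i = 0
        while i < L:
            mult = rate_scale(int(offsets[i]))
            p_del = cfg.indel_rate / 2 * scalar * mult
            p_sub = cfg.sub_rate * scalar * mult
            # a deletion never starts right after a deleted base: adjacent
            # deletions would merge in the alignment and blur the truth
            if rng.random() < p_del and not (i > 0 and deleted[i - 1]):
                length = min(_geometric_len(rng, cfg.indel_mean_len), L - i)
                deleted[i : i + length] = True
                truth.append({"species": sp, "offset": int(offsets[i]),
                              "kind": "deletion", "length": length})
                i += length
                continue
            if rng.random() < p_sub:
                choices = BASES[BASES != ref[i]]
                subbed[i] = rng.choice(choices)
                truth.append({"species": sp, "offset": int(offsets[i]),
                              "kind": "substitution", "length": 1})
            # insertions attach 3' of base i (never before the first base)
            if rng.random() < cfg.indel_rate / 2 * scalar * mult:
                length = _geometric_len(rng, cfg.indel_mean_len)
                inserts[i] = "".join(rng.choice(BASES, size=length))
                truth.append({"species": sp, "offset": int(offsets[i]),
                              "kind": "insertion", "length": length})
            i += 1
        species_rows[sp] = {"deleted": deleted, "subbed": subbed, "inserts": inserts}

    # assemble the merged alignment: one column per reference base, plus a
    # block of insert columns per (junction, species) so inserted bases from
    # different species never share a column
    names = ["reference", *cfg.species]
    cols = {name: [] for name in names}
    tss_column = None
    for i in range(L):
        if offsets[i] == 0:
            tss_column = len(cols["reference"])
        cols["reference"].append(ref[i])
        for sp in cfg.species:
            row = species_rows[sp]
            if row["deleted"][i]:
                cols[sp].append("-")
            elif i in row["subbed"]:
                cols[sp].append(row["subbed"][i])
            else:
                cols[sp].append(ref[i])
        for sp in cfg.species:
            ins = species_rows[sp]["inserts"].get(i)
            if ins:
                cols["reference"].extend("-" * len(ins))
                for other in cfg.species:
                    cols[other].extend(ins if other == sp else "-" * len(ins))
    rows = {name: "".join(c) for name, c in cols.items()}
    alignment = PromoterAlignment(gene=gene, ref_species="reference", rows=rows,
                                  tss_column=tss_column)
    return alignment, truth


def expand_truth_bits(
    truth: list[dict], species: str, upstream: int, downstream: int, mode: str = "all"
) -> np.ndarray:
    """Per-offset 0/1 truth coding for one species (the event-vector oracle)."""
    L = upstream + downstream
    base = np.zeros(L, dtype=np.uint8)
    indel = np.zeros(L, dtype=np.uint8)
    for ev in truth:
        if ev["species"] != species:
            continue
        idx = ev["offset"] + upstream
        if ev["kind"] == "substitution":
            base[idx] = 1
        elif ev["kind"] == "deletion":
            indel[idx : idx + ev["length"]] = 1
        else:  # insertion: single 1 at the 5' anchoring base
            indel[idx] = 1
    return {"base": base, "indel": indel, "all": base | indel}[mode]


def simulate_conservation_track(
    cfg: ConservationConfig,
    truth: list[dict],
    upstream: int,
    downstream: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-offset conservation scores: Gaussian background, depressed at events."""
    L = upstream + downstream
    values = rng.normal(cfg.background_mean, cfg.background_sd, size=L)
    hit = np.zeros(L, dtype=bool)
    for ev in truth:
        idx = ev["offset"] + upstream
        if ev["kind"] == "deletion":
            hit[idx : idx + ev["length"]] = True
        else:
            hit[idx] = True
    values[hit] -= cfg.depression
    return values


def simulate_cage(
    cfg: CageConfig, gene: str, rng: np.random.Generator
) -> tuple[SignalTrack, list[int], int]:
    """A CAGE track with Poisson-jittered peaks at candidate TSSs.

    Returns (track, candidate positions, truth dominant position). One
    candidate is scaled by the dominance factor.
    """
    values = np.zeros(cfg.track_length)
    margin = cfg.peak_halfwidth + 5
    candidates = sorted(
        rng.choice(np.arange(margin, cfg.track_length - margin),
                   size=cfg.n_candidates, replace=False).tolist()
    )
    dominant = int(candidates[int(rng.integers(cfg.n_candidates))])
    for pos in candidates:
        height = rng.uniform(*cfg.peak_height)
        if pos == dominant:
            height *= cfg.dominance
        for dx in range(-cfg.peak_halfwidth, cfg.peak_halfwidth + 1):
            values[pos + dx] += rng.poisson(height / (1 + abs(dx)))
    track = SignalTrack(GenomicInterval(f"chr_{gene}", 0, cfg.track_length), values)
    return track, candidates, dominant


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float, size) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(np.broadcast_to(mean, size)).astype(int)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, np.broadcast_to(p, size)).astype(int)


def simulate_expression(cfg: ExpressionConfig, rng: np.random.Generator):
    """Species count matrices, a hybrid allele table, and truth fold changes.

    Species B per-gene means are species A means scaled by 2^log2FC. In the
    cis_maintained scenario hybrid allele means keep the species ratio; in
    dominant_A/dominant_B one allele is fixed at 2^dominance_log2 times the
    other regardless of the species ratio. A configured fraction of genes
    is labelled chromosome X.
    """
    if cfg.hybrid_scenario not in ("cis_maintained", "dominant_A", "dominant_B"):
        raise ValueError(f"unknown hybrid scenario {cfg.hybrid_scenario!r}")
    genes = [f"g{i:04d}" for i in range(cfg.n_genes)]
    lengths = pd.Series(rng.integers(*cfg.length_range, size=cfg.n_genes), index=genes,
                        name="length")
    base_mean = rng.lognormal(np.log(cfg.nb_mean), 0.5, size=cfg.n_genes)
    truth_lfc = rng.normal(0.0, cfg.log2fc_sd, size=cfg.n_genes)
    mean_a = base_mean
    mean_b = base_mean * 2.0 ** truth_lfc
    reps = cfg.n_replicates
    counts_a = pd.DataFrame(
        _nb_draw(rng, mean_a[:, None], cfg.nb_dispersion, (cfg.n_genes, reps)),
        index=genes, columns=[f"A_rep{j+1}" for j in range(reps)],
    )
    counts_b = pd.DataFrame(
        _nb_draw(rng, mean_b[:, None], cfg.nb_dispersion, (cfg.n_genes, reps)),
        index=genes, columns=[f"B_rep{j+1}" for j in range(reps)],
    )
    n_x = int(round(cfg.x_fraction * cfg.n_genes))
    x_genes = set(rng.choice(genes, size=n_x, replace=False).tolist())
    chrom = pd.Series(["X" if g in x_genes else "2L" for g in genes], index=genes)

    if cfg.hybrid_scenario == "cis_maintained":
        hyb_a, hyb_b = mean_a / 2.0, mean_b / 2.0
    else:
        ratio = 2.0 ** cfg.dominance_log2
        total = (mean_a + mean_b) / 2.0
        if cfg.hybrid_scenario == "dominant_A":
            hyb_a = total * ratio / (1 + ratio)
            hyb_b = total / (1 + ratio)
        else:
            hyb_a = total / (1 + ratio)
            hyb_b = total * ratio / (1 + ratio)
    rows = []
    for allele, mu in (("A", hyb_a), ("B", hyb_b)):
        draws = _nb_draw(rng, mu[:, None], cfg.nb_dispersion, (cfg.n_genes, reps))
        for gi, g in enumerate(genes):
            rows.append({"gene": g, "chrom": chrom[g], "allele": allele,
                         **{f"hyb_rep{j+1}": int(draws[gi, j]) for j in range(reps)}})
    hybrid = pd.DataFrame(rows)
    truth = pd.DataFrame({"log2fc": truth_lfc, "chrom": chrom}, index=genes)
    truth["log2fc_ab"] = -truth["log2fc"]  # A vs B convention: mean_b = mean_a * 2^lfc
    return counts_a, counts_b, lengths, hybrid, truth


def simulate_tissue_matrix(cfg: TissueConfig, rng: np.random.Generator):
    """A gene x tissue matrix with planted tissue-specific genes and the truth list."""
    tissues = [f"tissue{i:02d}" for i in range(cfg.n_tissues)]
    target = tissues[0]
    rows, planted = {}, []
    for i in range(cfg.n_specific):
        g = f"spec{i:03d}"
        profile = rng.uniform(0, cfg.leakage * cfg.specific_level, size=cfg.n_tissues)
        profile[0] = cfg.specific_level
        rows[g] = profile
        planted.append(g)
    for i in range(cfg.n_uniform):
        g = f"unif{i:03d}"
        rows[g] = cfg.uniform_level * (1 + rng.uniform(-cfg.uniform_noise, cfg.uniform_noise,
                                                       size=cfg.n_tissues))
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=tissues)
    return matrix, target, planted


def write_dataset(cfg: SimConfig, outdir) -> dict:
    """Write a complete synthetic dataset as plain-text files plus truth JSON.

    Layout: alignments/*.fasta, tracks/*.bedgraph, tss.bed, counts_*.tsv,
    hybrid_counts.tsv, tissues.tsv, truth/*.json, manifest.json. Identical
    seeds produce byte-identical trees.
    """
    from . import io as pio

    outdir = Path(outdir)
    (outdir / "alignments").mkdir(parents=True, exist_ok=True)
    (outdir / "tracks").mkdir(exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    align_truth = {}
    tss_records = []
    for i in range(cfg.n_genes):
        gene = f"gene{i:03d}"
        aln, truth = simulate_promoter_alignment(cfg.alignment, gene, rng)
        pio.write_alignment_fasta(aln.rows, outdir / "alignments" / f"{gene}.fasta")
        align_truth[gene] = {"tss_column": aln.tss_column, "events": truth}
        cons = simulate_conservation_track(cfg.conservation, truth,
                                           cfg.alignment.upstream, cfg.alignment.downstream, rng)
        iv = GenomicInterval(f"chr_{gene}", 0, len(cons))
        pio.write_bedgraph(SignalTrack(iv, np.round(cons, 4)),
                           outdir / "tracks" / f"{gene}.phylop.bedgraph")
        cage_track, candidates, dominant = simulate_cage(cfg.cage, gene, rng)
        pio.write_bedgraph(cage_track, outdir / "tracks" / f"{gene}.cage.bedgraph")
        align_truth[gene]["cage_candidates"] = candidates
        align_truth[gene]["dominant_tss"] = dominant
        tss_records.append((gene, GenomicInterval(f"chr_{gene}", dominant, dominant + 1)))
    pio.write_tss_bed(tss_records, outdir / "tss.bed")

    counts_a, counts_b, lengths, hybrid, expr_truth = simulate_expression(cfg.expression, rng)
    pio.write_table(counts_a.assign(length=lengths), outdir / "counts_speciesA.tsv", index=True)
    pio.write_table(counts_b.assign(length=lengths), outdir / "counts_speciesB.tsv", index=True)
    pio.write_table(hybrid, outdir / "hybrid_counts.tsv")
    matrix, target, planted = simulate_tissue_matrix(cfg.tissue, rng)
    pio.write_table(matrix, outdir / "tissues.tsv", index=True)

    with open(outdir / "truth" / "alignments.json", "w") as fh:
        json.dump(align_truth, fh, indent=1, sort_keys=True)
    with open(outdir / "truth" / "expression.json", "w") as fh:
        json.dump({"log2fc_ab": expr_truth["log2fc_ab"].round(6).to_dict(),
                   "chrom": expr_truth["chrom"].to_dict(),
                   "scenario": cfg.expression.hybrid_scenario}, fh, indent=1, sort_keys=True)
    with open(outdir / "truth" / "tissues.json", "w") as fh:
        json.dump({"target_tissue": target, "planted": planted}, fh, indent=1)
    manifest = {"config": asdict(cfg), "n_genes": cfg.n_genes}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
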