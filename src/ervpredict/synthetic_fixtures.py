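"""Synthetic insertion tables and toy loci for fully self-contained runs.

The generator emulates the class-conditional structure observed in curated
mutagenic (positive) versus common fixed (negative) intronic ERV insertions:
positives are sense-enriched, sit in smaller introns and closer to exons.
Lengths are log-normal (normal in log10 bp), consistent with the log10
transform the encoder applies to correct the skewed genomic distribution of
intron sizes. All default effect sizes are synthetic conventions chosen to
mirror the direction and rough magnitude of those contrasts; they are not
measurements of any real dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import norm

from ervpredict.io_tables import ErvInsertion


@dataclass(frozen=True)
class SynthConfig:
    """Class-conditional generator settings.

    Counts default to the study scale (33 positives, 117 negatives, 134
    unlabeled polymorphic insertions). Orientation and family are Bernoulli
    per class; intron size and exon distance are 10**Normal(mean, sd) bp,
    with the distance drawn from that distribution truncated at half the
    intron size (an insertion can never be farther from the nearest exon
    than the intron midpoint).
    """

    n_pos: int = 33
    n_neg: int = 117
    n_polymorphic: int = 134
    p_sense_pos: float = 0.8
    p_sense_neg: float = 0.2
    p_etn_pos: float = 0.4
    p_etn_neg: float = 0.1
    intron_log10_mean_pos: float = 3.6
    intron_log10_mean_neg: float = 4.5
    intron_log10_sd: float = 0.5
    distance_log10_mean_pos: float = 2.8
    distance_log10_mean_neg: float = 3.8
    distance_log10_sd: float = 0.5
    # polymorphic set: mostly negative-like with a small positive-like share,
    # and an IAP-dominated family mix.
    positive_like_fraction: float = 0.07
    p_etn_polymorphic: float = 8 / 134
    seed: int = 0

    def __post_init__(self):
        for name in ("p_sense_pos", "p_sense_neg", "p_etn_pos", "p_etn_neg", "positive_like_fraction", "p_etn_polymorphic"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.intron_log10_sd <= 0 or self.distance_log10_sd <= 0:
            raise ValueError("log10 standard deviations must be positive")
        if min(self.n_pos, self.n_neg, self.n_polymorphic) < 1:
            raise ValueError("all record counts must be at least 1")


def _draw_lengths(rng, n, intron_mean, intron_sd, dist_mean, dist_sd):
    """Draw (intron_size, distance) pairs honoring distance <= intron/2.

    The distance is drawn from the log-normal truncated above at half the
    intron size by inverse-CDF sampling, which matches the distribution a
    rejection sampler would produce but cannot fail for small introns.
    """
    introns = np.maximum(1, np.round(10 ** rng.normal(intron_mean, intron_sd, size=n))).astype(int)
    limits = introns / 2.0
    upper = norm.cdf((np.log10(limits) - dist_mean) / dist_sd)
    u = rng.uniform(0.0, 1.0, size=n) * upper
    with np.errstate(divide="ignore"):  # ppf(0) = -inf maps cleanly to 0 bp
        x = dist_mean + dist_sd * norm.ppf(u)
    raw = np.maximum(0.0, np.round(10.0**x))
    distances = np.minimum(np.floor(limits), raw).astype(int)
    return introns, distances


def _make_records(rng, n, prefix, p_sense, p_etn, intron_mean, intron_sd, dist_mean, dist_sd, label, cfg) -> list:
    sense = rng.random(n) < p_sense
    etn = rng.random(n) < p_etn
    introns, distances = _draw_lengths(rng, n, intron_mean, intron_sd, dist_mean, dist_sd)
    return [
        ErvInsertion(
            id=f"{prefix}{i + 1:04d}",
            family="ETnMusD" if etn[i] else "IAP",
            orientation="sense" if sense[i] else "antisense",
            intron_size_bp=int(introns[i]),
            exon_distance_bp=int(distances[i]),
            label=label,
        )
        for i in range(n)
    ]


def generate_training_like(cfg: Optional[SynthConfig] = None) -> list[ErvInsertion]:
    """Labeled table: ``n_pos`` positives followed by ``n_neg`` negatives."""
    cfg = cfg or SynthConfig()
    if cfg.n_pos < 3 or cfg.n_neg < 3:
        raise ValueError("need at least 3 cases per class")
    rng = np.random.default_rng(cfg.seed)
    pos = _make_records(
        rng, cfg.n_pos, "pos", cfg.p_sense_pos, cfg.p_etn_pos,
        cfg.intron_log10_mean_pos, cfg.intron_log10_sd,
        cfg.distance_log10_mean_pos, cfg.distance_log10_sd, "positive", cfg,
    )
    neg = _make_records(
        rng, cfg.n_neg, "neg", cfg.p_sense_neg, cfg.p_etn_neg,
        cfg.intron_log10_mean_neg, cfg.intron_log10_sd,
        cfg.distance_log10_mean_neg, cfg.distance_log10_sd, "negative", cfg,
    )
    return pos + neg


def generate_polymorphic_like(cfg: Optional[SynthConfig] = None) -> list[ErvInsertion]:
    """Unlabeled table emulating an insertionally polymorphic ERV set.

    A small ``positive_like_fraction`` of records draws its lengths and
    orientation from the positive-class distributions, the rest from the
    negative-class ones; the family mix is IAP-dominated for all records.
    No labels are emitted.
    """
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    n = cfg.n_polymorphic
    latent_positive = rng.random(n) < cfg.positive_like_fraction
    records = []
    for i in range(n):
        if latent_positive[i]:
            p_sense, im, dm = cfg.p_sense_pos, cfg.intron_log10_mean_pos, cfg.distance_log10_mean_pos
        else:
            p_sense, im, dm = cfg.p_sense_neg, cfg.intron_log10_mean_neg, cfg.distance_log10_mean_neg
        intron, dist = _draw_lengths(rng, 1, im, cfg.intron_log10_sd, dm, cfg.distance_log10_sd)
        records.append(
            ErvInsertion(
                id=f"poly{i + 1:04d}",
                family="ETnMusD" if rng.random() < cfg.p_etn_polymorphic else "IAP",
                orientation="sense" if rng.random() < p_sense else "antisense",
                intron_size_bp=int(intron[0]),
                exon_distance_bp=int(dist[0]),
                label="unknown",
            )
        )
    return records


@dataclass
class ToyLocusSpec:
    """Layout of a small single-gene locus for annotation tests.

    ``exons`` are 0-based half-open intervals on ``chrom``; ``insertions``
    are (name, start, end, strand) tuples, with the family carried in the
    name as ``id|family``.
    """

    exons: list
    strand: str = "+"
    chrom: str = "chrT"
    gene_id: str = "toygene"
    insertions: list = field(default_factory=list)


def generate_toy_locus(spec: ToyLocusSpec) -> tuple[str, str]:
    """Render a layout spec as (GTF text, BED6 text).

    GTF exons are written 1-based closed; BED stays 0-based half-open.
    Overlapping exons in the spec are rejected.
    """
    exons = sorted(spec.exons)
    if len(exons) < 2:
        raise ValueError("a toy locus needs at least 2 exons")
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if s2 < e1:
            raise ValueError(f"exons [{s1},{e1}) and [{s2},{e2}) overlap")
    gtf_lines = []
    attrs = f'gene_id "{spec.gene_id}"; transcript_id "{spec.gene_id}.t1";'
    for start, end in exons:
        gtf_lines.append(
            "\t".join([spec.chrom, "toy", "exon", str(start + 1), str(end), ".", spec.strand, ".", attrs])
        )
    bed_lines = [
        "\t".join([spec.chrom, str(start), str(end), name, "0", strand])
        for name, start, end, strand in spec.insertions
    ]
    return "\n".join(gtf_lines) + "\n", "\n".join(bed_lines) + ("\n" if bed_lines else "")
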