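"""Synthetic four-group RNA-seq data with planted ground truth.

The generator emulates the study design every downstream stage assumes: four
groups (TL, PROM, PTB, PPROM) x 6 biological replicates, negative-binomial
counts over a synthetic annotation of lncRNAs and protein-coding genes on a
handful of chromosomes. It plants three kinds of recoverable structure:

* differential expression — single-group log2 shifts of +/-2 (fold change 4)
  on a set of genes, plus a few "key" lncRNAs shifted upward in both preterm
  groups (PTB and PPROM) so the contrast-pairing screen has a planted hit;
* regulatory pairs — lncRNA-mRNA pairs sharing a per-sample latent factor
  on the log scale, the loading calibrated by bisection so the sample
  Pearson correlation of log-expression hits a target (0.85 by default);
  a configurable fraction of pairs is genomically co-located within the
  cis window, the rest are trans by construction;
* an enriched gene set — one GMT term covering a fraction of the planted
  target mRNAs among size-matched random decoy terms.

Planted DE genes and planted pair members are disjoint, so the recovery of
each structure measures one analysis stage rather than a compound of
several. Counts additionally carry per-sample depth factors (log-uniform in
[0.7, 1.4]) that the size-factor normalization must absorb.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GeneTable, parse_gtf
from .expression import CountMatrix, GROUPS

DEFAULT_CONTRASTS = [
    "PROM_vs_TL", "PTB_vs_TL", "PPROM_vs_TL",
    "PTB_vs_PROM", "PPROM_vs_PROM", "PPROM_vs_PTB",
]

_LEN_RANGE = (500, 10_000)  # exonic length range, bp


@dataclass
class GroundTruth:
    """Planted structure emitted alongside the synthetic data.

    de_genes maps contrast -> {"up"|"down" -> {gene_id: planted log2fc}};
    regulatory_pairs has columns lncrna_id, gene_id, sign, colocated,
    target_r; group_shifts holds the per-gene per-group log2 shifts the
    contrasts derive from.
    """

    de_genes: dict[str, dict[str, dict[str, float]]]
    regulatory_pairs: pd.DataFrame
    enriched_term: str
    seed: int
    colocated: set[tuple[str, str]] = field(default_factory=set)
    group_shifts: pd.DataFrame | None = None
    pair_loading: float = 0.0

    def pair_set(self) -> set[tuple[str, str]]:
        return set(zip(self.regulatory_pairs["lncrna_id"], self.regulatory_pairs["gene_id"]))

    def target_genes(self) -> set[str]:
        return set(self.regulatory_pairs["gene_id"])

    def to_dir(self, truth_dir: str) -> None:
        os.makedirs(truth_dir, exist_ok=True)
        rows = [
            (contrast, direction, gene, lfc)
            for contrast, dirs in self.de_genes.items()
            for direction, genes in dirs.items()
            for gene, lfc in sorted(genes.items())
        ]
        pd.DataFrame(rows, columns=["contrast", "direction", "gene_id", "planted_log2fc"]).to_csv(
            os.path.join(truth_dir, "de_genes.tsv"), sep="\t", index=False
        )
        self.regulatory_pairs.to_csv(
            os.path.join(truth_dir, "regulatory_pairs.tsv"), sep="\t", index=False
        )
        with open(os.path.join(truth_dir, "meta.json"), "w") as fh:
            json.dump(
                {"enriched_term": self.enriched_term, "seed": self.seed,
                 "pair_loading": self.pair_loading},
                fh, indent=2, sort_keys=True,
            )


def _exon_structure(rng: np.random.Generator, exonic_len: int) -> list[tuple[int, int]]:
    """Split an exonic length into 1-3 exons with intron gaps; offsets from 0."""
    n_exons = int(rng.integers(1, 4))
    while n_exons > 1 and exonic_len < 100 * n_exons:
        n_exons -= 1
    if n_exons == 1:
        sizes = [exonic_len]
    else:
        cuts = np.sort(rng.choice(np.arange(100, exonic_len - 100 * (n_exons - 1) + 1, 100),
                                  size=n_exons - 1, replace=False))
        bounds = [0, *cuts.tolist(), exonic_len]
        sizes = [bounds[i + 1] - bounds[i] for i in range(n_exons)]
    introns = rng.integers(50, 2001, size=n_exons - 1)
    exons, pos = [], 0
    for i, size in enumerate(sizes):
        exons.append((pos, pos + size))
        pos += size
        if i < n_exons - 1:
            pos += int(introns[i])
    return exons


def generate_annotation(
    n_lncrna: int = 300,
    n_mrna: int = 2000,
    n_chrom: int = 5,
    frac_colocated: float = 0.3,
    window: int = 100_000,
    seed: int = 0,
) -> tuple[str, GeneTable, set[tuple[str, str]]]:
    """Synthetic GTF with designated co-located lncRNA-mRNA partners.

    Returns (gtf_text, parsed GeneTable, co-location truth). For
    ``frac_colocated`` of the lncRNAs one designated mRNA sits within the
    window (gap uniform in [0, window]); every other lncRNA x mRNA
    combination is separated by more than the window, so the truth set is
    exactly the designated pairs.
    """
    if n_lncrna < 1 or n_mrna < 1 or n_chrom < 1:
        raise ValueError("gene and chromosome counts must be >= 1")
    if not (0.0 <= frac_colocated <= 1.0):
        raise ValueError("frac_colocated must lie in [0, 1]")
    rng = np.random.default_rng([1, seed])

    lnc_ids = [f"LNC{i:04d}" for i in range(1, n_lncrna + 1)]
    mrna_ids = [f"GENE{i:05d}" for i in range(1, n_mrna + 1)]
    n_pairs = int(round(frac_colocated * n_lncrna))
    n_pairs = min(n_pairs, n_mrna)
    paired_lnc = sorted(rng.choice(lnc_ids, size=n_pairs, replace=False).tolist())
    paired_mrna = sorted(rng.choice(mrna_ids, size=n_pairs, replace=False).tolist())
    partner = dict(zip(paired_lnc, paired_mrna))

    # slots: a designated pair shares one slot; everything else sits alone.
    slots: list[list[tuple[str, str]]] = [
        [(l, "lncRNA"), (partner[l], "protein_coding")] for l in paired_lnc
    ]
    slots += [[(l, "lncRNA")] for l in lnc_ids if l not in partner]
    used_mrna = set(paired_mrna)
    slots += [[(m, "protein_coding")] for m in mrna_ids if m not in used_mrna]
    order = rng.permutation(len(slots))
    chrom_of_slot = rng.integers(0, n_chrom, size=len(slots))

    lines: list[str] = []
    cursors = {f"chr{i + 1}": 1_000 for i in range(n_chrom)}
    colocated: set[tuple[str, str]] = set()
    for slot_idx, chrom_idx in zip(order, chrom_of_slot):
        chrom = f"chr{chrom_idx + 1}"
        pos = cursors[chrom]
        slot = slots[slot_idx]
        ends = []
        for member_idx, (gene_id, biotype) in enumerate(slot):
            exonic_len = int(rng.integers(_LEN_RANGE[0], _LEN_RANGE[1] + 1))
            exons = _exon_structure(rng, exonic_len)
            strand = "+" if rng.random() < 0.5 else "-"
            span = exons[-1][1]
            attrs = f'gene_id "{gene_id}"; gene_biotype "{biotype}";'
            lines.append(
                f"{chrom}\tlncnet_sim\tgene\t{pos + 1}\t{pos + span}\t.\t{strand}\t.\t{attrs}"
            )
            for es, ee in exons:
                lines.append(
                    f"{chrom}\tlncnet_sim\texon\t{pos + es + 1}\t{pos + ee}\t.\t{strand}\t.\t{attrs}"
                )
            ends.append(pos + span)
            if member_idx < len(slot) - 1:
                pos = pos + span + int(rng.integers(0, window + 1))  # within-slot gap
        if len(slot) == 2:
            colocated.add((slot[0][0], slot[1][0]))
        cursors[chrom] = max(ends) + window + 1 + int(rng.integers(0, 20_001))

    gtf_text = "\n".join(lines) + "\n"
    return gtf_text, parse_gtf(gtf_text), colocated


def _calibrate_pair_loading(
    target_r: float,
    mu_range: tuple[float, float],
    dispersion: float,
    n_samples: int,
    seed: int,
    n_probe: int = 300,
    approx_library_size: float = 3.0e5,
) -> float:
    """Bisect the latent-factor loading b (log2 units) so that simulated
    pairs reach a median sample Pearson r of ``target_r`` on log2(FPKM+1).

    ``approx_library_size`` stands in for the per-sample column total of the
    eventual count matrix so the probe can be transformed on the same
    log2(FPKM+1) scale the analysis uses; probe lengths are drawn from the
    annotation length range.
    """

    def median_r(b: float) -> float:
        rng = np.random.default_rng([2, seed, int(b * 1e9)])
        mu = np.exp(rng.uniform(np.log(mu_range[0]), np.log(mu_range[1]), size=(2, n_probe)))
        length = np.exp(rng.uniform(np.log(_LEN_RANGE[0]), np.log(_LEN_RANGE[1]), size=(2, n_probe)))
        z = rng.standard_normal((n_probe, n_samples))
        rs = np.empty(n_probe)
        for i in range(n_probe):
            mean = mu[:, i][:, None] * 2.0 ** (b * z[i][None, :])
            r_nb = 1.0 / dispersion
            counts = rng.negative_binomial(r_nb, r_nb / (r_nb + mean))
            x = np.log2(counts * (1e9 / (length[:, i][:, None] * approx_library_size)) + 1.0)
            xc = x - x.mean(axis=1, keepdims=True)
            denom = np.sqrt((xc[0] ** 2).sum() * (xc[1] ** 2).sum())
            rs[i] = (xc[0] * xc[1]).sum() / denom if denom > 0 else 0.0
        return float(np.median(rs))

    lo, hi = 0.02, 4.0
    for _ in range(18):
        mid = 0.5 * (lo + hi)
        if median_r(mid) < target_r:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_counts(
    annotation: GeneTable,
    colocated: set[tuple[str, str]],
    groups: tuple[str, ...] = GROUPS,
    n_replicates: int = 6,
    n_de_per_contrast: int = 150,
    planted_log2fc: float = 2.0,
    base_mu_range: tuple[float, float] = (20.0, 500.0),
    dispersion: float = 0.05,
    n_pairs: int = 200,
    pair_target_r: float = 0.85,
    positive_fraction: float = 0.7,
    n_key_lncrna: int = 2,
    depth_range: tuple[float, float] = (0.7, 1.4),
    contrasts: list[str] | None = None,
    seed: int = 0,
) -> tuple[CountMatrix, GroundTruth]:
    """NB count matrix over the annotation with planted DE, pairs, and depth.

    DE is planted as single-group log2 shifts: each group receives
    ``n_de_per_contrast // 2`` shifted genes (half up, half down), so each
    pairwise contrast carries ~``n_de_per_contrast`` planted DE genes. Key
    lncRNAs are shifted up in both preterm groups (PTB, PPROM). Regulatory
    pairs reuse the annotation's designated co-located partners as cis pairs
    and add trans pairs from leftover genes; each pair shares a per-sample
    standard-normal latent factor with calibrated loading (negated on the
    mRNA for negative pairs).
    """
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates per group")
    if not (0.0 <= positive_fraction <= 1.0):
        raise ValueError("positive_fraction must lie in [0, 1]")
    if dispersion <= 0 or planted_log2fc <= 0:
        raise ValueError("dispersion and planted_log2fc must be positive")
    if contrasts is None:
        contrasts = [c for c in DEFAULT_CONTRASTS
                     if all(g in groups for g in c.split("_vs_"))]
    rng = np.random.default_rng([3, seed])

    lnc_ids = sorted(annotation.ids_of_biotype("lncRNA"))
    mrna_ids = sorted(annotation.ids_of_biotype("protein_coding"))
    genes = lnc_ids + mrna_ids
    gene_index = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)
    samples = [f"{g}_{i + 1}" for g in groups for i in range(n_replicates)]
    n_samples = len(samples)
    group_of = np.repeat(np.arange(len(groups)), n_replicates)

    # --- regulatory pairs: cis from the designated partners, the rest trans
    cis_pairs = sorted(colocated)
    if len(cis_pairs) > n_pairs:
        idx = rng.choice(len(cis_pairs), size=n_pairs, replace=False)
        cis_pairs = [cis_pairs[i] for i in sorted(idx)]
    n_trans = n_pairs - len(cis_pairs)
    used_lnc = {l for l, _ in cis_pairs}
    used_mrna = {m for _, m in cis_pairs}
    free_lnc = [l for l in lnc_ids if l not in used_lnc]
    free_mrna = [m for m in mrna_ids if m not in used_mrna]
    if n_trans > min(len(free_lnc), len(free_mrna)):
        raise ValueError("not enough genes for the requested number of trans pairs")
    trans_l = rng.choice(free_lnc, size=n_trans, replace=False)
    trans_m = rng.choice(free_mrna, size=n_trans, replace=False)
    trans_pairs = sorted(zip(trans_l.tolist(), trans_m.tolist()))
    all_pairs = cis_pairs + trans_pairs
    signs = np.where(rng.random(len(all_pairs)) < positive_fraction, 1, -1)

    # --- planted DE: disjoint from pair members
    pair_members = {g for p in all_pairs for g in p}
    eligible_lnc = [l for l in lnc_ids if l not in pair_members]
    eligible_mrna = [m for m in mrna_ids if m not in pair_members]
    if n_key_lncrna > len(eligible_lnc):
        raise ValueError("not enough lncRNAs left for key-lncRNA planting")
    key_lnc = sorted(rng.choice(eligible_lnc, size=n_key_lncrna, replace=False).tolist())
    eligible = sorted(set(eligible_lnc + eligible_mrna) - set(key_lnc))
    n_per_group = n_de_per_contrast // 2
    n_de_total = n_per_group * len(groups)
    if n_de_total > len(eligible):
        raise ValueError("not enough genes left for the requested DE planting")
    de_choice = rng.choice(eligible, size=n_de_total, replace=False)

    shifts = np.zeros((n_genes, len(groups)))
    for gi, grp in enumerate(groups):
        block = de_choice[gi * n_per_group:(gi + 1) * n_per_group]
        for j, gene in enumerate(block):
            sign = 1.0 if j % 2 == 0 else -1.0
            shifts[gene_index[gene], gi] = sign * planted_log2fc
    preterm = [i for i, g in enumerate(groups) if g in ("PTB", "PPROM")]
    for gene in key_lnc:
        shifts[gene_index[gene], preterm] = planted_log2fc

    # --- latent pair factors
    loading = 0.0 if not all_pairs else _calibrate_pair_loading(
        pair_target_r, base_mu_range, dispersion, n_samples, seed
    )
    latent = np.zeros((n_genes, n_samples))
    z = rng.standard_normal((len(all_pairs), n_samples))
    for p, ((l, m), s) in enumerate(zip(all_pairs, signs)):
        latent[gene_index[l]] += loading * z[p]
        latent[gene_index[m]] += s * loading * z[p]

    # --- NB sampling
    mu = np.exp(rng.uniform(np.log(base_mu_range[0]), np.log(base_mu_range[1]), size=n_genes))
    depth = np.exp(rng.uniform(np.log(depth_range[0]), np.log(depth_range[1]), size=n_samples))
    log2_mean = (
        np.log2(mu)[:, None] + np.log2(depth)[None, :]
        + shifts[:, group_of] + latent
    )
    mean = 2.0 ** log2_mean
    r_nb = 1.0 / dispersion
    counts = rng.negative_binomial(r_nb, r_nb / (r_nb + mean))

    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    design = pd.Series([groups[i] for i in group_of], index=samples, name="group")
    cm = CountMatrix(counts_df, design)

    de_genes: dict[str, dict[str, dict[str, float]]] = {}
    for contrast in contrasts:
        b, a = contrast.split("_vs_")
        delta = shifts[:, groups.index(b)] - shifts[:, groups.index(a)]
        de_genes[contrast] = {
            "up": {genes[i]: float(delta[i]) for i in np.nonzero(delta > 0)[0]},
            "down": {genes[i]: float(delta[i]) for i in np.nonzero(delta < 0)[0]},
        }

    pairs_df = pd.DataFrame(
        {
            "lncrna_id": [l for l, _ in all_pairs],
            "gene_id": [m for _, m in all_pairs],
            "sign": ["positive" if s > 0 else "negative" for s in signs],
            "colocated": [(l, m) in colocated for l, m in all_pairs],
            "target_r": pair_target_r,
        }
    )
    truth = GroundTruth(
        de_genes=de_genes,
        regulatory_pairs=pairs_df,
        enriched_term="",
        seed=seed,
        colocated=set(colocated),
        group_shifts=pd.DataFrame(shifts, index=genes, columns=list(groups)),
        pair_loading=loading,
    )
    return cm, truth


def generate_gene_sets(
    annotation: GeneTable,
    truth: GroundTruth,
    n_terms: int = 25,
    planted_coverage: float = 0.6,
    term_size: int = 50,
    seed: int = 0,
) -> tuple[str, str]:
    """GMT text with one planted target-enriched term among random decoys.

    The planted term contains round(planted_coverage * n_targets) true
    target mRNAs (capped at the term size), padded with random non-target
    mRNAs; decoys are size-matched uniform draws from all mRNAs. Returns
    (gmt_text, planted_term_id) and records the term id in the truth.
    """
    if len(truth.regulatory_pairs) == 0:
        raise ValueError("truth has no regulatory pairs to build a planted term from")
    rng = np.random.default_rng([4, seed])
    mrna_ids = sorted(annotation.ids_of_biotype("protein_coding"))
    targets = sorted(truth.target_genes())
    n_true = min(int(round(planted_coverage * len(targets))), term_size)
    members = sorted(rng.choice(targets, size=n_true, replace=False).tolist())
    non_targets = [m for m in mrna_ids if m not in set(targets)]
    if term_size - n_true > 0:
        members += sorted(rng.choice(non_targets, size=term_size - n_true, replace=False).tolist())

    planted_id = "TERM_PLANTED"
    lines = [planted_id + "\ttarget-enriched set\t" + "\t".join(sorted(members))]
    for t in range(1, n_terms):
        decoy = sorted(rng.choice(mrna_ids, size=term_size, replace=False).tolist())
        lines.append(f"TERM{t:03d}\tdecoy set {t}\t" + "\t".join(decoy))
    truth.enriched_term = planted_id
    return "\n".join(lines) + "\n", planted_id


def generate_dataset(outdir: str, seed: int = 0, **params) -> GroundTruth:
    """Emit annotation.gtf, counts.tsv, design.tsv, genesets.gmt and truth/.

    ``params`` may override any keyword of :func:`generate_annotation`,
    :func:`generate_counts` or :func:`generate_gene_sets`.
    """
    ann_keys = {"n_lncrna", "n_mrna", "n_chrom", "frac_colocated", "window"}
    set_keys = {"n_terms", "planted_coverage", "term_size"}
    ann_kw = {k: v for k, v in params.items() if k in ann_keys}
    set_kw = {k: v for k, v in params.items() if k in set_keys}
    cnt_kw = {k: v for k, v in params.items() if k not in ann_keys | set_keys}

    os.makedirs(outdir, exist_ok=True)
    gtf_text, annotation, colocated = generate_annotation(seed=seed, **ann_kw)
    cm, truth = generate_counts(annotation, colocated, seed=seed, **cnt_kw)
    gmt_text, _ = generate_gene_sets(annotation, truth, seed=seed, **set_kw)

    with open(os.path.join(outdir, "annotation.gtf"), "w") as fh:
        fh.write(gtf_text)
    cm.counts.to_csv(os.path.join(outdir, "counts.tsv"), sep="\t", index_label="gene_id")
    cm.design.rename_axis("sample_id").to_frame("group").to_csv(
        os.path.join(outdir, "design.tsv"), sep="\t"
    )
    with open(os.path.join(outdir, "genesets.gmt"), "w") as fh:
        fh.write(gmt_text)
    truth.to_dir(os.path.join(outdir, "truth"))
    return truth
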