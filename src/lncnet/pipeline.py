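"""End-to-end orchestration: counts -> FPKM -> DE -> target map -> screens.

Stage order mirrors the analysis flow: normalization, per-contrast NB
differential expression at the study thresholds, lncRNA-mRNA co-expression
with cis/trans labeling against the genomic window, direction-aware
multi-contrast overlap screening with Fisher's exact test, and
hypergeometric enrichment of the target sets. All outputs are plain TSV /
GraphML / SIF with deterministic ordering; rerunning an identical config
reproduces every file byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import os
import shutil
from dataclasses import dataclass, field, asdict

import pandas as pd
import yaml

from . import annotation as ann
from . import coexpression as coexpr
from . import de
from . import enrichment as enrich
from . import expression as expr
from . import sets as setan
from .sets import DEFAULT_PAIRING_SCHEME
from .simulate import DEFAULT_CONTRASTS


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths, thresholds and flags for one pipeline run."""

    counts: str = ""
    design: str = ""
    gtf: str = ""
    gmt: str = ""
    outdir: str = "lncnet_out"
    de_p: float = 0.01
    fc: float = 2.0
    r_threshold: float = 0.6
    coexp_p: float = 0.01
    cis_window: int = 100_000
    min_fpkm: float = 0.1
    min_samples: int = 2
    n_pcs: int = 2
    contrasts: list[str] = field(default_factory=lambda: list(DEFAULT_CONTRASTS))
    pairing_scheme: list[list[str]] = field(
        default_factory=lambda: [list(p) for p in DEFAULT_PAIRING_SCHEME]
    )
    seed: int = 0
    strict_fc: bool = False
    per_group_correlation: bool = False
    trans_includes_colocated: bool = False
    lncrna_selection: str = "expressed"  # or "de_union"

    def validate(self) -> None:
        if not (0.0 < self.de_p < 1.0) or not (0.0 < self.coexp_p <= 1.0):
            raise ValueError("p-value thresholds out of range")
        if self.fc <= 1.0 or not (0.0 <= self.r_threshold <= 1.0):
            raise ValueError("fc must be > 1 and r_threshold in [0, 1]")
        if self.cis_window < 0 or self.min_fpkm < 0 or self.min_samples < 0:
            raise ValueError("window and filter thresholds must be >= 0")
        if self.lncrna_selection not in ("expressed", "de_union"):
            raise ValueError("lncrna_selection must be 'expressed' or 'de_union'")
        for path_attr in ("counts", "design", "gtf", "gmt"):
            path = getattr(self, path_attr)
            if not path or not os.path.exists(path):
                raise FileNotFoundError(f"config.{path_attr}: no such file: {path!r}")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def sha256(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()


def run_pipeline(config: PipelineConfig) -> str:
    """Run every stage and return the output directory.

    Any stage failure raises :class:`PipelineError` naming the stage, after
    removing the files this run had already produced.
    """
    config.validate()
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    written: list[str] = []
    log_lines: list[str] = [f"lncnet pipeline\nconfig_sha256\t{config.sha256()}\nseed\t{config.seed}"]

    def emit(relpath: str, writer) -> str:
        path = os.path.join(outdir, relpath)
        os.makedirs(os.path.dirname(path) or outdir, exist_ok=True)
        writer(path)
        written.append(path)
        return path

    def log(stage: str, **counts) -> None:
        kv = "\t".join(f"{k}={v}" for k, v in counts.items())
        log_lines.append(f"{stage}\t{kv}")

    stage = "setup"
    try:
        stage = "load"
        annotation = ann.parse_gtf(open(config.gtf).read())
        cm = expr.CountMatrix.from_tsv(config.counts, config.design)
        gene_sets = enrich.parse_gmt(open(config.gmt).read())
        log(stage, genes=len(cm.genes), samples=len(cm.samples),
            annotated=len(annotation), terms=len(gene_sets))

        stage = "fpkm"
        fpkm = expr.compute_fpkm(cm, annotation)
        filtered = expr.filter_expressed(fpkm, config.min_fpkm, config.min_samples)
        emit("fpkm.tsv", lambda p: filtered.fpkm.to_csv(p, sep="\t", index_label="gene_id"))
        expressed = set(filtered.genes)
        expressed_lnc = [g for g in filtered.genes if annotation[g].biotype == "lncRNA"]
        expressed_mrna = [g for g in filtered.genes if annotation[g].biotype == "protein_coding"]
        log(stage, expressed=len(expressed), lncrna=len(expressed_lnc),
            mrna=len(expressed_mrna))

        stage = "pca"
        if len(expressed_lnc) >= 2 and 0 < config.n_pcs < len(cm.samples):
            scores = expr.pca_scores(filtered.subset(expressed_lnc), config.n_pcs)
            emit("pca_lncrna.tsv", lambda p: scores.to_csv(p, sep="\t", index_label="sample_id"))
            log(stage, components=config.n_pcs)

        stage = "differential_expression"
        factors = de.size_factors(cm)
        called_by_contrast: dict[str, pd.DataFrame] = {}
        for contrast in config.contrasts:
            table = de.call_degs(
                de.de_contrast(cm, contrast, factors),
                config.de_p, config.fc, config.strict_fc,
            )
            called_by_contrast[contrast] = table
            emit(f"de/{contrast}.tsv", lambda p, t=table: t.to_csv(p, sep="\t", index=False))
        table1 = de.deg_count_table(called_by_contrast)
        emit("table1.tsv", lambda p: table1.to_csv(p, sep="\t", index=False))
        log(stage, **{c: int(t) for c, t in zip(table1["contrast"], table1["total"])})

        stage = "coexpression"
        lnc_sets = {
            c: de.deg_sets(t[t["gene_id"].isin(expressed_lnc)])
            for c, t in called_by_contrast.items()
        }
        if config.lncrna_selection == "de_union":
            selected_lnc = sorted(
                set().union(*(s["up"] | s["down"] for s in lnc_sets.values()))
            )
        else:
            selected_lnc = list(expressed_lnc)
        pairs = coexpr.coexpressed_pairs(
            filtered.subset(selected_lnc),
            filtered.subset(expressed_mrna),
            config.r_threshold,
            config.coexp_p,
            scope="within_group" if config.per_group_correlation else "pooled",
        )
        colocated = ann.colocated_pairs(
            annotation, selected_lnc, expressed_mrna, config.cis_window
        )
        pairs = coexpr.label_cis_trans(pairs, colocated)
        emit("pairs.tsv", lambda p: pairs.to_csv(p, sep="\t", index=False))
        summary = coexpr.network_summary(pairs)
        emit("table2.tsv", lambda p: summary.to_frame().to_csv(p, sep="\t", index=False))
        de_direction = {
            c: dict(zip(t["gene_id"], t["direction"])) for c, t in called_by_contrast.items()
        }
        graphml = os.path.join(outdir, "network.graphml")
        sif = os.path.join(outdir, "network.sif")
        coexpr.export_network(pairs, graphml, sif, de_direction)
        written += [graphml, sif]
        log(stage, pairs=summary.all_pairs, cis=int((pairs["relation"] == "cis").sum()),
            trans=int((pairs["relation"] == "trans").sum()))

        stage = "overlap_screen"
        scheme = [tuple(p) for p in config.pairing_scheme]
        # a pairing may reference the reverse of a computed contrast; by the
        # exact label-swap symmetry of the NB test, reversed up = forward down
        screen_sets = dict(lnc_sets)
        for contrast_a, contrast_b, _label in scheme:
            for name in (contrast_a, contrast_b):
                if name not in screen_sets:
                    b, a = de.parse_contrast(name)
                    reverse = f"{a}_vs_{b}"
                    if reverse not in screen_sets:
                        raise ValueError(
                            f"pairing scheme contrast {name!r} has no computed "
                            f"contrast or reverse"
                        )
                    screen_sets[name] = {
                        "up": screen_sets[reverse]["down"],
                        "down": screen_sets[reverse]["up"],
                    }
        overlaps, candidates = setan.key_lncrna_screen(
            screen_sets, universe_size=len(expressed_lnc), scheme=scheme
        )
        emit("overlaps.tsv",
             lambda p: setan.overlaps_to_frame(overlaps).to_csv(p, sep="\t", index=False))
        emit("key_lncrnas.tsv", lambda p: candidates.to_csv(p, sep="\t", index=False))
        log(stage, pairings=len(scheme), candidates=len(candidates))

        stage = "enrichment"
        universe = set(expressed_mrna)
        cis_targets = set(pairs.loc[pairs["relation"] == "cis", "gene_id"])
        if config.trans_includes_colocated:
            trans_targets = set(pairs["gene_id"])
        else:
            trans_targets = set(pairs.loc[pairs["relation"] == "trans", "gene_id"])
        queries = {
            "cis_targets": cis_targets,
            "trans_targets": trans_targets,
            "all_targets": set(pairs["gene_id"]),
        }
        for name, query in queries.items():
            result = enrich.hypergeom_enrich(query & universe, gene_sets, universe)
            emit(f"enrichment/{name}.tsv",
                 lambda p, r=result: r.to_csv(p, sep="\t", index=False))
            log(stage + ":" + name, query=len(query), terms=len(result))

        stage = "finalize"
        emit("effective_config.yaml", lambda p: config.to_yaml(p))
        emit("run_log.txt", lambda p: open(p, "w").write("\n".join(log_lines) + "\n"))
    except Exception as exc:
        for path in written:
            if os.path.exists(path):
                os.remove(path)
        for sub in ("de", "enrichment"):
            subdir = os.path.join(outdir, sub)
            if os.path.isdir(subdir) and not os.listdir(subdir):
                shutil.rmtree(subdir)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc
    return outdir
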