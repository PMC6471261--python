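"""End-to-end orchestration: preprocess → annotate → quantify → diffexpr
→ profiles → targets → enrichment (→ qPCR), with stable output filenames
under a run directory and a deterministic run manifest.

Stage errors are re-raised wrapped with the stage name and offending
file so a failed run names its culprit.  The manifest records the tool
version, a config hash, and per-output sha256 checksums and row counts;
identical config + inputs reproduce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import COMPARISONS, RunConfig, TIMEPOINTS
from .sequence_io import (
    read_annotation_tsv, read_expression_tsv, read_fasta, read_fastq, log_stage,
)
from . import preprocess as pp
from .annotate import ReferenceSet, classify_tags
from .quantify import expression_matrix, family_abundance
from .diffexpr import call_dems, dem_frame
from . import stem_profiles as stem
from .targets import anti_correlate, pairs_frame, scan_transcriptome
from .enrichment import enrich, report_table, results_frame
from . import qpcr_validation as qpcr

log = logging.getLogger("mejamir")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _row_count(path: Path) -> int:
    with open(path) as fh:
        return sum(1 for _ in fh)


def comparison_label(a: str, b: str) -> str:
    return f"{a}_vs_{b}"


def run_all(config: RunConfig, input_dir, out_dir,
            stem_permutations: int | None = None) -> dict:
    """Run every stage on the inputs in `input_dir`; returns the manifest."""
    inp = Path(input_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    libs = config.samples.libraries
    thr = config.thresholds
    outputs: list[Path] = []

    def register(path: Path) -> None:
        outputs.append(path)

    # ---------------- preprocess ----------------
    stage = "preprocess"
    try:
        reads = {lib: read_fastq(inp / f"{lib}.fastq") for lib in libs}
        tags, report = pp.collapse_tags(reads, config.adapter3, config.adapter5)
        if not report.balanced():
            raise StageError(stage, "filter report does not balance")
        totals = pp.total_clean_tags(tags, libs)
        pp.write_clean_tags_fasta(out / "clean_tags.fa", tags)
        report.to_frame().to_csv(out / "filter_report.tsv", sep="\t")
        register(out / "clean_tags.fa")
        register(out / "filter_report.tsv")
        log_stage(stage, sum(report.raw.values()), len(tags))
    except StageError:
        raise
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # ---------------- annotate ----------------
    stage = "annotate"
    try:
        mature = read_fasta(inp / "mature_ref.fa")
        fam_path = inp / "mature_families.tsv"
        if fam_path.exists():
            fams = dict(line.split("\t")[:2] for line in
                        fam_path.read_text().splitlines() if line)
        else:
            fams = {mid: mid.split("-")[0] for mid in mature}
        refs = ReferenceSet(
            mature_mirnas=mature,
            mature_families=fams,
            other_ncrna=read_fasta(inp / "ncrna_ref.fa"),
            transcriptome=read_fasta(inp / "transcriptome.fa"),
        )
        annotations, hairpins = classify_tags(tags, refs)
        ann_df = pd.DataFrame([
            {"tag": a.tag_id, "seq": a.seq, "category": a.category,
             "hit": a.hit[0] if a.hit else "", "family": a.family or "",
             "mirna_id": a.mirna_id or ""}
            for a in annotations])
        ann_df.to_csv(out / "annotations.tsv", sep="\t", index=False)
        hp_df = pd.DataFrame([
            {"tag": tid, "contig": h.contig, "window_start": h.window_start,
             "window_end": h.window_end, "arm": h.arm,
             "paired_bases": h.paired_bases, "fold_score": h.fold_score,
             "star_seq": h.star_seq}
            for tid, h in hairpins.items()])
        hp_df.to_csv(out / "hairpins.tsv", sep="\t", index=False)
        register(out / "annotations.tsv")
        register(out / "hairpins.tsv")
        log_stage(stage, len(tags), len(annotations))
    except StageError:
        raise
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # ---------------- quantify ----------------
    stage = "quantify"
    try:
        counts, tpms, families = expression_matrix(annotations, tags, libs, totals)
        counts.rename_axis("mirna").to_csv(out / "mirna_counts.tsv", sep="\t")
        tpms.rename_axis("mirna").to_csv(out / "mirna_tpm.tsv", sep="\t")
        fam_table = family_abundance(counts, families, config.samples.timepoint)
        fam_table.rename_axis("family").to_csv(out / "family_presence.tsv", sep="\t")
        for f in ("mirna_counts.tsv", "mirna_tpm.tsv", "family_presence.tsv"):
            register(out / f)
        log_stage(stage, len(tags), len(counts))
    except StageError:
        raise
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # ---------------- diffexpr ----------------
    stage = "diffexpr"
    dems: dict[str, list] = {}
    try:
        for a, b in COMPARISONS:
            label = comparison_label(a, b)
            res = call_dems(tpms, counts, totals,
                            config.samples.group(a), config.samples.group(b),
                            label, thr.fold_change, thr.de_p)
            dems[label] = res
            df = dem_frame(res)
            df.to_csv(out / f"dem_{label}.tsv", sep="\t", index=False)
            register(out / f"dem_{label}.tsv")
        log_stage(stage, len(counts),
                  sum(sum(r.significant for r in v) for v in dems.values()))
    except StageError:
        raise
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # ---------------- stem profiles ----------------
    stage = "stem"
    try:
        dem_ids = sorted({r.mirna for v in dems.values() for r in v if r.significant})
        profiles = stem.enumerate_profiles()
        if dem_ids:
            tp_means = {
                tp: tpms.loc[dem_ids, config.samples.group(tp)].mean(axis=1)
                for tp in TIMEPOINTS}
            vectors = {
                m: stem.standardize(np.array([tp_means[tp][m] for tp in TIMEPOINTS]))
                for m in dem_ids}
            assignments = stem.assign(vectors, profiles)
            prof_df = stem.profile_significance(
                assignments, profiles,
                n_permutations=(stem_permutations or config.stem_permutations),
                seed=config.seed, alpha=thr.stem_p)
            asg_df = pd.DataFrame([
                {"mirna": a.mirna, "profile_id": a.profile_id,
                 "correlation": a.correlation,
                 "vector": ",".join(f"{v:.4f}" for v in a.vector)}
                for a in assignments])
        else:
            prof_df = pd.DataFrame(columns=["profile_id", "shape", "gene_count",
                                            "expected", "p_value", "significant"])
            asg_df = pd.DataFrame(columns=["mirna", "profile_id", "correlation",
                                           "vector"])
        prof_df.to_csv(out / "stem_profiles.tsv", sep="\t", index=False)
        asg_df.to_csv(out / "stem_assignments.tsv", sep="\t", index=False)
        register(out / "stem_profiles.tsv")
        register(out / "stem_assignments.tsv")
        log_stage(stage, len(dem_ids), len(prof_df))
    except StageError:
        raise
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # ---------------- targets ----------------
    stage = "targets"
    try:
        mirna_seqs = {}
        for a in annotations:
            if a.mirna_id:
                mirna_seqs.setdefault(a.mirna_id, a.seq)
        transcriptome = refs.transcriptome
        pairs = scan_transcriptome(mirna_seqs, transcriptome)
        mrna_path = inp / "mrna_expr.tsv"
        if mrna_path.exists():
            mrna = read_expression_tsv(mrna_path, libs)
            n_before = len(pairs)
            pairs = anti_correlate(pairs, tpms, mrna,
                                   thr.cor_threshold, thr.cor_p)
            if n_before != len(pairs):
                log.info("targets: dropped %d pairs without expression",
                         n_before - len(pairs))
        df = pairs_frame(pairs)
        tcols = ["mirna", "gene", "site_start", "site_end", "mismatch_score",
                 "e_dup", "e_perf", "ratio"]
        (df[tcols] if len(df) else pd.DataFrame(columns=tcols)).to_csv(
            out / "targets.tsv", sep="\t", index=False)
        df.to_csv(out / "pairs.tsv", sep="\t", index=False)
        register(out / "targets.tsv")
        register(out / "pairs.tsv")
        log_stage(stage, len(mirna_seqs), len(pairs))
    except StageError:
        raise
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # ---------------- enrichment ----------------
    stage = "enrichment"
    try:
        ann_path = inp / "pathway_annotation.tsv"
        if not ann_path.exists():
            raise StageError(stage, f"missing annotation table {ann_path}")
        annotation = read_annotation_tsv(ann_path)
        targets_of = {}
        for p in pairs:
            targets_of.setdefault(p.mirna, set()).add(p.gene)
        enr_results = {}
        n_per_comp = {}
        for a, b in COMPARISONS:
            label = comparison_label(a, b)
            sig = {r.mirna for r in dems[label] if r.significant}
            deg_targets = set().union(*(targets_of.get(m, set()) for m in sig)) \
                if sig else set()
            results, dropped = enrich(deg_targets, annotation)
            if dropped:
                log.info("enrichment %s: %d target genes lack annotation",
                         label, dropped)
            enr_results[label] = results
            n_per_comp[label] = len(deg_targets & annotation.genes)
            results_frame(results).to_csv(
                out / f"enrichment_{label}.tsv", sep="\t", index=False)
            register(out / f"enrichment_{label}.tsv")
        row_names = sorted({r.name for v in enr_results.values() for r in v})
        tbl = report_table(enr_results, row_names,
                           {k: max(v, 1) for k, v in n_per_comp.items()})
        tbl.rename_axis("pathway").to_csv(out / "table1.tsv", sep="\t")
        register(out / "table1.tsv")
        log_stage(stage, len(annotation.genes),
                  sum(len(v) for v in enr_results.values()))
    except StageError:
        raise
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # ---------------- qpcr (optional) ----------------
    ct_path = inp / "ct_table.tsv"
    if ct_path.exists():
        stage = "qpcr"
        try:
            records = qpcr.read_ct_table(ct_path)
            rels = qpcr.relative_expression(records)
            folds = pd.DataFrame([
                {"mirna": r.mirna, "timepoint": r.timepoint, "fold": r.fold,
                 "sd": r.sd, "fold_low": r.fold_low, "fold_high": r.fold_high}
                for r in rels])
            folds.to_csv(out / "qpcr_folds.tsv", sep="\t", index=False)
            register(out / "qpcr_folds.tsv")
            lfc = {}
            for tp in ("T1", "T2", "T3"):
                label = comparison_label("CK", tp)
                for r in dems[label]:
                    lfc[(r.mirna, tp)] = r.log2fc
            try:
                conc = qpcr.concordance(rels, lfc)
                conc.to_csv(out / "concordance.tsv", sep="\t", index=False)
                register(out / "concordance.tsv")
            except ValueError:
                log.info("qpcr: no assayed miRNA matched the expression matrix")
        except StageError:
            raise
        except Exception as e:
            raise StageError(stage, str(e)) from e

    # ---------------- manifest ----------------
    cfg_hash = hashlib.sha256(
        yaml.safe_dump(json.loads(json.dumps({
            "adapter3": config.adapter3, "adapter5": config.adapter5,
            "seed": config.seed,
            "thresholds": vars(thr),
        }))).encode()).hexdigest()
    manifest = {
        "version": __version__,
        "config_hash": cfg_hash,
        "outputs": {
            p.name: {"sha256": _sha256(p), "rows": _row_count(p)}
            for p in outputs
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
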