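"""End-to-end orchestration: simulate -> call -> scan -> score -> structure -> protein.

One seeded configuration drives every stage; all randomness flows from the
single seed, so a rerun with the same config produces byte-identical
outputs (JSON is written with sorted keys and no timestamps; per-stage
timings go to the logger only).
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass

import pandas as pd
import yaml

from . import association, calling, scoring, simulate, structure
from .proteins import annotate_consequences

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    seed: int
    outdir: str
    panel: simulate.PanelConfig | None = None  # defaults to PanelConfig(seed=seed)
    q: float = 0.05
    k_values: tuple[int, ...] = (1, 2, 3)
    bootstrap_B: int = 2000
    threshold: float = 0.0

    def __post_init__(self):
        if not 0 < self.q < 1:
            raise ValueError("q must lie in (0, 1)")
        if self.panel is None:
            self.panel = simulate.PanelConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        panel = data.pop("panel", None)
        cfg = cls(**data)
        if panel:
            cfg.panel = simulate.PanelConfig(seed=data.get("seed", 0), **panel)
        return cfg


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def call_panel(records, references) -> dict[str, list[calling.VariantCall]]:
    """Align every per-sample record to its gene's reference and call variants."""
    refs = {r.name: r for r in references}
    calls: dict[str, list[calling.VariantCall]] = {}
    for rec in records:
        ref = refs[rec.gene]
        aln = calling.align_global(rec, ref)
        calls.setdefault(rec.sample, []).extend(calling.call_variants(aln, ref))
    return calls


def run_all(config: RunConfig) -> dict:
    """Run the whole pipeline and write a machine-readable report.

    Emits variant tables, scan results, score specs per k, evaluation JSON,
    MDS coordinates, protein annotations, and summary JSON + Markdown under
    ``config.outdir``. Returns the report dict.
    """
    os.makedirs(config.outdir, exist_ok=True)
    report: dict = {"seed": config.seed, "q": config.q}

    panel = _stage("simulate")(simulate.simulate_panel)(config.panel)
    chem = _stage("chemotypes")(simulate.simulate_chemotable)(config.panel)
    simulate.write_panel(panel, os.path.join(config.outdir, "panel"))
    chem_path = os.path.join(config.outdir, "chemotypes.csv")

    # variant discovery by alignment against the references
    calls = _stage("call")(call_panel)(panel.records, panel.references)
    calling.write_variant_table(calls, os.path.join(config.outdir, "calls.tsv"))
    labels = panel.metadata.set_index("sample_id")["class"]
    matrix = calling.build_matrix(calls, labels)
    matrix.cells.to_csv(os.path.join(config.outdir, "genotypes.csv"))
    report["n_samples"] = len(matrix.samples)
    report["n_loci"] = int(matrix.cells.shape[1])

    scan = _stage("scan")(association.scan_loci)(matrix, q=config.q)
    scan.to_csv(os.path.join(config.outdir, "scan.tsv"), sep="\t")
    sig = scan[scan["significant"]]
    report["n_significant"] = int(len(sig))

    if sig.empty:
        report["scoring"] = "skipped: no significant loci at q"
        log.warning("no significant loci at q=%s; scoring stage skipped", config.q)
    else:
        snp_keys = [k for k in sig.index if sig.loc[k, "kind"] == "snp"]
        profile = scoring.consensus_profile(matrix, snp_keys) if snp_keys else (
            pd.DataFrame(columns=["drug_allele", "fiber_allele"])
        )
        profile.to_csv(os.path.join(config.outdir, "consensus_profile.csv"))
        report["scores"] = {}
        for k in config.k_values:
            if k > len(sig):
                continue
            spec = _stage(f"optimize k={k}")(scoring.optimize_weights)(
                matrix, profile, k=k
            )
            spec.to_json(os.path.join(config.outdir, f"score_spec_k{k}.json"))
            result = scoring.evaluate(
                spec, matrix, profile, B=config.bootstrap_B, seed=config.seed
            )
            report["scores"][f"k={k}"] = {
                "loci": spec.loci, "weights": spec.weights,
                **result.as_dict(),
            }
        # the published fixed-weight deletion/insertion score
        try:
            indel_spec = scoring.indel_score_spec(matrix, threshold=config.threshold)
            indel_eval = scoring.evaluate(
                indel_spec, matrix, profile, B=config.bootstrap_B, seed=config.seed
            )
            report["indel_score"] = {
                "loci": indel_spec.loci, "weights": indel_spec.weights,
                **indel_eval.as_dict(),
            }
        except ValueError:
            report["indel_score"] = "no indel loci in panel"

    # population structure and chemotypes
    chem_annot = structure.chem_ratio_and_group(chem)
    chem_annot.to_csv(chem_path, index=False)
    D = _stage("gower")(structure.gower_distance)(matrix)
    D.to_csv(os.path.join(config.outdir, "gower_distances.csv"))
    coords = structure.classical_mds(D, dims=2)
    coords.to_csv(os.path.join(config.outdir, "mds_coordinates.csv"))
    group_of_variety = chem_annot.set_index("variety")["group"]
    groups = panel.metadata.set_index("sample_id")["variety"].map(group_of_variety)
    entropy = structure.entropy_summary(matrix, groups)
    report["entropy"] = {
        "overall": entropy["overall"],
        "within": {str(k): v for k, v in entropy["within"].items()},
        "between": entropy["between"],
    }

    # protein consequences of the planted drug/fiber differences
    ref_a, ref_b = panel.references
    truth = panel.truth
    protein_report = {}
    for ref, klass in ((ref_a, "fiber"), (ref_b, "drug")):
        # the mutant gene carries the non-reference class's planted alleles
        allele_col = "drug_allele" if klass == "drug" else "fiber_allele"
        rows = truth.loci[truth.loci["gene"] == ref.name]
        variants = []
        for _, r in rows.iterrows():
            if r["kind"] == "snp":
                ref_allele = ref.cds[r["position"] - 1]
                variants.append(calling.VariantCall(
                    ref.name, int(r["position"]), "snp", ref_allele, r[allele_col]
                ))
            elif r["kind"] == "deletion" and klass == "drug":
                span = simulate.DELETION_SPAN
                variants.append(calling.VariantCall(
                    ref.name, span[0], "deletion",
                    ref.cds[span[0] - 1 : span[1]], ""
                ))
            elif r["kind"] == "insertion" and klass == "drug":
                variants.append(calling.VariantCall(
                    ref.name, simulate.INSERTION_POSITION, "insertion",
                    "", simulate.INSERTED_BASES
                ))
        annotations, summary = _stage(f"protein {ref.name}")(annotate_consequences)(
            ref, variants
        )
        pd.DataFrame([a.__dict__ for a in annotations]).to_csv(
            os.path.join(config.outdir, f"protein_{ref.name}.tsv"),
            sep="\t", index=False,
        )
        summary["ratio"] = None if summary["n_syn"] == 0 else summary["ratio"]
        protein_report[ref.name] = summary
    report["protein"] = protein_report

    report_path = os.path.join(config.outdir, "report.json")
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _write_markdown(report, os.path.join(config.outdir, "report.md"))
    return report


def _write_markdown(report: dict, path) -> None:
    lines = ["# cannamark pipeline report", ""]
    lines.append(f"- samples: {report.get('n_samples')}")
    lines.append(f"- loci genotyped: {report.get('n_loci')}")
    lines.append(f"- significant loci (q={report['q']}): {report.get('n_significant')}")
    scores = report.get("scores")
    if isinstance(scores, dict):
        lines.append("")
        lines.append("| score | AUC | sensitivity | specificity |")
        lines.append("|---|---|---|---|")
        for name, s in scores.items():
            lines.append(
                f"| {name} | {s['auc']:.4f} | {s['sensitivity']:.4f} | {s['specificity']:.4f} |"
            )
        indel = report.get("indel_score")
        if isinstance(indel, dict):
            lines.append(
                f"| indel (+1.1/-1) | {indel['auc']:.4f} | {indel['sensitivity']:.4f} "
                f"| {indel['specificity']:.4f} |"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
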