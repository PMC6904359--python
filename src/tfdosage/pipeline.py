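"""End-to-end orchestration: classify -> enrich -> compare -> ora -> report.

A run is driven by one YAML config with per-stage sections; all outputs are
TSV plus a JSON run manifest recording the resolved config, input digests,
per-stage effective sample sizes and timestamps.  All randomness lives in
the simulator — the analysis stages are deterministic, so re-running on
identical inputs reproduces identical output digests.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
import os

import pandas as pd

from . import __version__
from .catalog import (
    EvidenceSets,
    read_gene_set,
    read_gene_table,
    read_gmt,
    read_motifs,
    records_to_frame,
)
from .classifier import classify, label_sets, labels_to_frame, venn_partition
from .enrichment import (
    DEFAULT_SMALL_FAMILY_CUTOFFS,
    build_family_groups,
    run_enrichment,
)
from .features import compare_feature, compare_motifs, summarize_expression
from .ora import run_ora
from .synthdata import SimulationConfig, generate

logger = logging.getLogger("tfdosage")

ALL_STAGES = ("classify", "enrich", "compare", "ora")

DEFAULT_COMPARE_FEATURES = (
    "cds_length", "dnds", "ppi_degree", "ppi_tf_fraction", "mrna_level", "dbd_size",
)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, int):
        return str(value)
    if isinstance(value, float):
        return "0" if value == 0 else f"{value:.4g}"
    return str(value)


def _write_tsv(rows: list[dict], columns: list[str], path: str) -> None:
    with open(path, "wt", encoding="utf-8", newline="") as handle:
        handle.write("\t".join(columns) + "\n")
        for row in rows:
            handle.write("\t".join(_fmt(row.get(c)) for c in columns) + "\n")


def _digest(path: str) -> str:
    sha = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            sha.update(chunk)
    return sha.hexdigest()


def load_inputs(paths: dict) -> dict:
    """Read catalog, evidence sets and optional motif/GMT inputs.

    ``paths`` carries ``catalog``, the six set files (``conserved_cnv`` ...
    ``hlof_consang``; HLOF sets optional) and optional ``motifs``/``gmt``.
    Every referenced file is checked for existence before anything is read
    (fail-fast), so a typo cannot leave partial outputs behind.
    """
    required = ["catalog"] + list(EvidenceSets.EVIDENCE_NAMES)
    missing = [k for k in required if k not in paths]
    if missing:
        raise FileNotFoundError(f"missing input entries: {missing}")
    for key, path in paths.items():
        if key in ("outdir",):
            continue
        if not os.path.exists(path):
            raise FileNotFoundError(f"input {key!r}: no such file {path}")

    records = read_gene_table(paths["catalog"])
    frame = records_to_frame(records)
    sets = {}
    for name in EvidenceSets.EVIDENCE_NAMES + EvidenceSets.HLOF_NAMES:
        if name in paths:
            sets[name] = read_gene_set(paths[name])
    evidence = EvidenceSets.from_sets(set(frame["gene_id"]), **sets)
    data = {"frame": frame, "evidence": evidence, "motifs": None, "terms": None}
    if "motifs" in paths:
        data["motifs"] = read_motifs(paths["motifs"])
    if "gmt" in paths:
        data["terms"] = read_gmt(paths["gmt"])
    return data


def run_all(
    config: dict | str,
    outdir: str | None = None,
    stages: tuple[str, ...] = ALL_STAGES,
) -> str:
    """Execute the pipeline per config; returns the output directory.

    ``config`` is a YAML path or an equivalent dict with keys:

    * ``outdir`` — output directory;
    * either ``simulate`` (a :class:`SimulationConfig` mapping) or
      ``inputs`` (file paths, see :func:`load_inputs`);
    * optional ``classify``/``enrich``/``compare``/``ora`` sections.
    """
    import yaml

    if isinstance(config, str):
        with open(config, "rt", encoding="utf-8") as handle:
            config = yaml.safe_load(handle)
    config = dict(config)
    outdir = outdir or config.get("outdir")
    if not outdir:
        raise ValueError("an output directory is required")
    unknown = [s for s in stages if s not in ALL_STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")

    manifest: dict = {
        "tool": "tfdosage",
        "version": __version__,
        "started": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": {k: v for k, v in config.items() if k != "simulate"},
        "stages": list(stages),
        "inputs": {},
        "outputs": {},
        "effective_n": {},
    }

    if "simulate" in config:
        sim_config = SimulationConfig.from_dict(config["simulate"] or {})
        manifest["config"]["simulate"] = sim_config.to_dict()
        data = generate(sim_config)
        frame, evidence = data.frame, data.evidence
        motifs, terms = data.motifs, data.terms
        samples = data.expression_samples
        os.makedirs(outdir, exist_ok=True)
        sim_paths = data.write(os.path.join(outdir, "simulated"))
        manifest["inputs"] = {k: _digest(v) for k, v in sim_paths.items()}
    else:
        paths = config.get("inputs") or {}
        loaded = load_inputs(paths)
        frame, evidence = loaded["frame"], loaded["evidence"]
        motifs, terms = loaded["motifs"], loaded["terms"]
        samples = sorted(
            {
                s
                for levels in frame["expression_levels"]
                if isinstance(levels, dict)
                for s in levels
            }
        )
        os.makedirs(outdir, exist_ok=True)
        manifest["inputs"] = {
            k: _digest(v) for k, v in paths.items() if os.path.isfile(str(v))
        }

    threshold = float((config.get("classify") or {}).get("threshold", 0.5))
    labels = classify(frame, evidence, score_threshold=threshold)
    mrds, mrdis = label_sets(labels)
    manifest["effective_n"]["classify"] = {
        "universe": len(labels), "mrds": len(mrds), "mrdis": len(mrdis),
    }

    if "classify" in stages:
        labels_path = os.path.join(outdir, "labels.tsv")
        labels_to_frame(labels).to_csv(labels_path, sep="\t", index=False)
        manifest["outputs"]["labels"] = _digest(labels_path)
        venn = venn_partition(evidence)
        venn_path = os.path.join(outdir, "venn.tsv")
        _write_tsv(
            [
                {"signature": sig, "count": count}
                for sig, count in sorted(venn.region_counts.items())
            ],
            ["signature", "count"],
            venn_path,
        )
        manifest["outputs"]["venn"] = _digest(venn_path)

    if "enrich" in stages:
        enrich_cfg = config.get("enrich") or {}
        cutoffs = tuple(
            enrich_cfg.get("small_family_cutoffs", DEFAULT_SMALL_FAMILY_CUTOFFS)
        )
        yates = bool(enrich_cfg.get("yates", False))
        families = build_family_groups(frame)
        universe = set(frame["gene_id"])
        targets = {
            "mrds": mrds,
            "mrdis": mrdis,
            "hlof_pnull": evidence.hlof_pnull,
            "hlof_consang": evidence.hlof_consang,
        }
        for target_name, target in targets.items():
            if not target:
                logger.warning("target set %s is empty; skipped", target_name)
                continue
            results = run_enrichment(
                target, families, universe, small_family_cutoffs=cutoffs, yates=yates
            )
            rows = [
                {
                    "group": r.group_name,
                    "n_group": r.n_group,
                    "observed": r.observed,
                    "expected": r.expected,
                    "statistic": r.statistic,
                    "test_used": r.test_used,
                    "direction": r.direction,
                    "p": r.p,
                    "p_adj": r.p_adj,
                }
                for r in sorted(results, key=lambda r: (r.p_adj, r.group_name))
            ]
            path = os.path.join(outdir, f"enrichment_{target_name}.tsv")
            _write_tsv(
                rows,
                ["group", "n_group", "observed", "expected", "statistic",
                 "test_used", "direction", "p", "p_adj"],
                path,
            )
            manifest["outputs"][f"enrichment_{target_name}"] = _digest(path)
            manifest["effective_n"][f"enrichment_{target_name}"] = len(rows)

    if "compare" in stages:
        compare_cfg = config.get("compare") or {}
        feature_names = compare_cfg.get("features", list(DEFAULT_COMPARE_FEATURES))
        restrict = "tf_only" if compare_cfg.get("tf_only", True) else "all_genes"
        rows = []
        for feature in feature_names:
            try:
                result = compare_feature(frame, labels, feature, restrict=restrict)
            except ValueError as exc:
                logger.warning("compare %s skipped: %s", feature, exc)
                continue
            rows.append(result)
        if motifs:
            try:
                rows.extend(compare_motifs(motifs, labels))
            except ValueError as exc:
                logger.warning("motif comparison skipped: %s", exc)
        if samples:
            try:
                _, expr = summarize_expression(frame, labels, samples)
                rows.extend(expr)
            except ValueError as exc:
                logger.warning("expression comparison skipped: %s", exc)
        path = os.path.join(outdir, "comparisons.tsv")
        _write_tsv(
            [
                {
                    "feature": r.feature,
                    "n_mrds": r.n_a, "mean_mrds": r.mean_a, "sd_mrds": r.sd_a,
                    "n_mrdis": r.n_b, "mean_mrdis": r.mean_b, "sd_mrdis": r.sd_b,
                    "u": r.u_statistic, "p": r.p,
                }
                for r in rows
            ],
            ["feature", "n_mrds", "mean_mrds", "sd_mrds",
             "n_mrdis", "mean_mrdis", "sd_mrdis", "u", "p"],
            path,
        )
        manifest["outputs"]["comparisons"] = _digest(path)
        manifest["effective_n"]["compare"] = {
            r.feature: [r.n_a, r.n_b] for r in rows
        }

    if "ora" in stages and terms:
        ora_cfg = config.get("ora") or {}
        alpha = float(ora_cfg.get("alpha", 0.05))
        universe_mode = ora_cfg.get("universe", "annotated")
        tf_mask = frame["is_tf"].astype(bool)
        tf_ids = set(frame.loc[tf_mask, "gene_id"])
        rows = []
        for study_name, study in (
            ("mrds_tf", mrds & tf_ids), ("mrdis_tf", mrdis & tf_ids),
        ):
            if not study:
                logger.warning("ORA study set %s empty; skipped", study_name)
                continue
            for r in run_ora(
                study, terms, set(frame["gene_id"]),
                alpha=alpha, universe_mode=universe_mode,
            ):
                rows.append(
                    {
                        "study": study_name, "term": r.term_id,
                        "term_size": r.term_size, "overlap": r.overlap,
                        "expected": r.expected_overlap, "p": r.p, "p_adj": r.p_adj,
                    }
                )
        path = os.path.join(outdir, "terms.tsv")
        _write_tsv(
            rows,
            ["study", "term", "term_size", "overlap", "expected", "p", "p_adj"],
            path,
        )
        manifest["outputs"]["terms"] = _digest(path)

    manifest["finished"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
    with open(os.path.join(outdir, "manifest.json"), "wt", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return outdir


def render_report(outdir: str) -> str:
    """Render run outputs as a Markdown report; returns the report path.

    The report shows each enrichment table (total / observed / expected /
    adjusted p, significant rows marked) and the feature comparisons as
    mean +/- SD per class.  Regeneration is idempotent.
    """
    manifest_path = os.path.join(outdir, "manifest.json")
    if not os.path.exists(manifest_path):
        raise FileNotFoundError(f"missing artifact: {manifest_path}")
    with open(manifest_path, "rt", encoding="utf-8") as handle:
        manifest = json.load(handle)

    lines = ["# tfdosage run report", ""]
    counts = manifest.get("effective_n", {}).get("classify", {})
    if counts:
        lines += [
            f"Universe: {counts.get('universe')} genes; "
            f"MRDS: {counts.get('mrds')}; MRDIS: {counts.get('mrdis')}.",
            "",
        ]
    for name in ("mrds", "mrdis", "hlof_pnull", "hlof_consang"):
        path = os.path.join(outdir, f"enrichment_{name}.tsv")
        if f"enrichment_{name}" in manifest.get("outputs", {}) and not os.path.exists(path):
            raise FileNotFoundError(f"missing artifact: {path}")
        if not os.path.exists(path):
            continue
        table = pd.read_csv(path, sep="\t")
        lines.append(f"## Enrichment vs {name.upper()}")
        lines.append("")
        lines.append("| Group | Total | Observed | Expected | adjusted p | |")
        lines.append("|---|---|---|---|---|---|")
        for row in table.itertuples(index=False):
            mark = "*" if row.p_adj < 0.05 else ""
            lines.append(
                f"| {row.group} | {row.n_group} | {row.observed} |"
                f" {_fmt(float(row.expected))} | {_fmt(float(row.p_adj))} | {mark} |"
            )
        lines.append("")
    comp_path = os.path.join(outdir, "comparisons.tsv")
    if os.path.exists(comp_path):
        table = pd.read_csv(comp_path, sep="\t")
        lines.append("## MRDS vs MRDIS feature comparisons")
        lines.append("")
        lines.append("| Feature | MRDS (mean ± SD, n) | MRDIS (mean ± SD, n) | p |")
        lines.append("|---|---|---|---|")
        for row in table.itertuples(index=False):
            lines.append(
                f"| {row.feature} |"
                f" {_fmt(float(row.mean_mrds))} ± {_fmt(float(row.sd_mrds))}"
                f" (n={row.n_mrds}) |"
                f" {_fmt(float(row.mean_mrdis))} ± {_fmt(float(row.sd_mrdis))}"
                f" (n={row.n_mrdis}) | {_fmt(float(row.p))} |"
            )
        lines.append("")
    report_path = os.path.join(outdir, "report.md")
    with open(report_path, "wt", encoding="utf-8", newline="") as handle:
        handle.write("\n".join(lines) + "\n")
    return report_path
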