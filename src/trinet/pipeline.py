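"""End-to-end orchestration: simulate/load -> preprocess -> network ->
triplets -> pathway screen, with one root seed and a machine-readable
run report.

The run is configured by a single YAML mapping::

    seed: 1
    simulate:              # either this block ...
      n_samples: 300
      n_mrna: 50
      ...
    inputs:                # ... or this one
      mrna: mrna.tsv
      lncrna: lnc.tsv
      mirna: mir.tsv       # or: noncoding: nc.tsv
    preprocess:
      log_base: 2
      apply_log: true
      mirna_patterns: ["hsa-mir", "hsa-let", "mir", "let-7"]
    network:
      cutoff: 0.8
      presample_size: 200
      initial_wealth: 0.05
      payout: 0.05
      max_passes: 2
    screen:
      gmt: pathways.gmt
      set_id: hsa05213

All artifact writers are deterministic, so rerunning an identical config
reproduces byte-identical files.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import yaml

from . import io as tio
from .exceptions import ValidationError
from .genesets import select_gene_set
from .network import IntegrativeNetworkBuilder, degree_summary, enumerate_tasks
from .preprocess import DEFAULT_MIRNA_PREFIXES, preprocess
from .regression import VifParams
from .simulate import SimConfig, generate_dataset, recovery_metrics
from .triplets import find_heterogeneous_triangles, screen_by_pathway, \
    triplet_census

logger = logging.getLogger(__name__)

STALE_MARKER = "STALE"


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    return cfg


def _load_inputs(cfg: dict):
    inputs = cfg.get("inputs")
    sim = cfg.get("simulate")
    if (inputs is None) == (sim is None):
        raise ValidationError(
            "config needs exactly one of 'inputs' or 'simulate'")
    if sim is not None:
        sim = dict(sim)
        sim.setdefault("seed", int(cfg.get("seed", 0)))
        mrna, lnc, mirna, truth = generate_dataset(SimConfig(**sim))
        return mrna, lnc, mirna, None, truth
    mrna = tio.read_expression(inputs["mrna"], rna_type="mRNA")
    lnc = tio.read_expression(inputs["lncrna"], rna_type="lncRNA")
    mirna = noncoding = None
    if "mirna" in inputs:
        mirna = tio.read_expression(inputs["mirna"], rna_type="miRNA")
    elif "noncoding" in inputs:
        noncoding = tio.read_expression(inputs["noncoding"],
                                        rna_type="lncRNA")
    else:
        raise ValidationError("inputs needs 'mirna' or 'noncoding'")
    return mrna, lnc, mirna, noncoding, None


def run_all(config, out_dir) -> dict:
    """Execute the full pipeline; returns the run report (also written).

    ``config`` is a mapping or a YAML path.  On any stage failure a
    ``STALE`` marker naming the failed stage is left in ``out_dir`` so
    partial artifacts are recognizable, and the error propagates.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stale = out / STALE_MARKER
    stage = "setup"
    try:
        seed = int(config.get("seed", 0))
        t0 = time.perf_counter()

        stage = "load-inputs"
        mrna, lnc, mirna, noncoding, truth = _load_inputs(config)
        if truth is not None:
            tio.write_expression(mrna, out / "mrna.tsv")
            tio.write_expression(lnc, out / "lncrna.tsv")
            tio.write_expression(mirna, out / "mirna.tsv")
            tio.write_triplets(truth.triplets, out / "truth_triplets.tsv")

        stage = "preprocess"
        pp = dict(config.get("preprocess") or {})
        combined = preprocess(
            mrna, lnc, mirna, noncoding=noncoding,
            mirna_patterns=tuple(pp.get("mirna_patterns",
                                        DEFAULT_MIRNA_PREFIXES)),
            log_base=float(pp.get("log_base", 2.0)),
            apply_log=bool(pp.get("apply_log", True)))
        tio.write_expression(combined, out / "combined.tsv")
        logger.info("preprocess: %d genes x %d samples (%.1fs)",
                    combined.n_genes, combined.n_samples,
                    time.perf_counter() - t0)

        stage = "build-network"
        net_cfg = dict(config.get("network") or {})
        cutoff = float(net_cfg.pop("cutoff", 0.8))
        params = VifParams(seed=seed, **net_cfg)
        builder = IntegrativeNetworkBuilder(cutoff=cutoff, params=params)
        builder.fit(combined)
        graph = builder.graph_
        tio.write_edges(graph, out / "edges.tsv")
        logger.info("network: %d vertices, %d edges, %d/%d models retained",
                    graph.n_vertices, graph.n_edges,
                    builder.result_.n_retained, builder.result_.n_tasks)

        stage = "find-triplets"
        triplets = find_heterogeneous_triangles(graph)
        tio.write_triplets(triplets, out / "triplets.tsv")

        screened = None
        screen_cfg = config.get("screen")
        if screen_cfg:
            stage = "screen"
            genesets = tio.read_gmt(screen_cfg["gmt"])
            gs = select_gene_set(genesets, screen_cfg.get("set_id", ""),
                                 union=bool(screen_cfg.get("union", False)))
            screened = screen_by_pathway(triplets, gs)
            tio.write_triplets(screened, out / "screened.tsv")

        stage = "report"
        tasks = enumerate_tasks(combined)
        report = {
            "seed": seed,
            "n_genes": combined.n_genes,
            "n_samples": combined.n_samples,
            "genes_per_type": combined.type_counts(),
            "task_count": len(tasks),
            "predictors_per_task": tasks[0].n_predictors,
            "retained_models": builder.result_.n_retained,
            "zero_variance_genes": builder.result_.n_skipped_zero_variance,
            "cutoff": cutoff,
            "network": degree_summary(graph),
            "triplets": triplet_census(triplets),
        }
        if screened is not None:
            report["screened"] = triplet_census(screened)
        if truth is not None:
            rec = recovery_metrics(triplets, truth)
            report["recovery"] = {
                "precision": rec.precision, "recall": rec.recall,
                "f1": rec.f1, "degenerate": rec.degenerate,
            }
        with open(out / "report.json", "w", encoding="utf-8",
                  newline="\n") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        if stale.exists():
            stale.unlink()
        return report
    except Exception as exc:
        stale.write_text(f"stage {stage} failed: {exc}\n", encoding="utf-8")
        raise
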