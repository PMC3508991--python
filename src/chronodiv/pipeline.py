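"""End-to-end orchestration of the diversification + biogeography analysis.

One config drives the whole chain: read trees -> prune outgroups ->
gamma/CR and MCCR tests -> model comparison -> LTT/MLTT -> interval
birth rates -> branch-length CDF -> DIVA on the consensus tree and
S-DIVA over the tree sample.  Every stage writes its own TSV/JSON, a
consolidated ``report.json`` collects everything, and a MANIFEST records
which stages completed; identical inputs and seed reproduce every
stochastic section bit-identically.

Defaults that encode the reference study's settings: interval width 0.9
Ma, clade species total 70, maximum ancestral-range size 2, 50 trees in
the multiple-LTT plot.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .treeio import (
    TreeSample,
    branch_lengths,
    branching_times,
    drop_taxa,
    read_trees,
)
from .divstats import (
    branch_length_cdf,
    gamma_statistic,
    interval_rates,
    ltt_curve,
    mccr_test,
    mltt,
)
from .modelfit import compare_models
from .biogeo import diva_optimize, read_range_table, sdiva_summarize

log = logging.getLogger("chronodiv")

__all__ = ["AnalysisConfig", "run_pipeline", "load_config"]


@dataclass
class AnalysisConfig:
    """Flat configuration of one pipeline run."""

    tree_path: str = ""                 # consensus chronogram (newick/nexus)
    tree_format: str = "newick"
    sample_path: str | None = None      # posterior-like tree sample
    sample_format: str = "newick"
    range_path: str | None = None       # taxon<TAB>areas TSV
    outgroups: tuple[str, ...] = ()
    delta_t: float = 0.9                # Ma, interval-rate bin width
    n_total: int = 70                   # described species in the clade
    mccr_reps: int = 1000
    max_areas: int = 2
    mltt_k: int = 50
    models: tuple[str, ...] = ("pureBirth", "yule2rate")
    seed: int = 0
    out_dir: str = "chronodiv_out"
    figures: bool = False

    def validate(self) -> None:
        if not self.tree_path:
            raise ValueError("tree_path is required")
        for p in (self.tree_path, self.sample_path, self.range_path):
            if p and not Path(p).exists():
                raise FileNotFoundError(p)
        for name in ("delta_t", "n_total", "mccr_reps", "max_areas", "mltt_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def load_config(path: str) -> AnalysisConfig:
    """Parse a flat ``key = value`` config file."""
    kwargs: dict = {}
    tuple_fields = {"outgroups", "models"}
    types = AnalysisConfig.__dataclass_fields__
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if key not in types:
            raise ValueError(f"unknown config key: {key}")
        if key in tuple_fields:
            kwargs[key] = tuple(v.strip() for v in val.split(",") if v.strip())
        else:
            target = types[key].type
            if "bool" in str(target):
                kwargs[key] = val.lower() in ("1", "true", "yes")
            elif "int" in str(target):
                kwargs[key] = int(val)
            elif "float" in str(target):
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
    return AnalysisConfig(**kwargs)


# ---------------------------------------------------------------------------
# serialisation helpers
# ---------------------------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, dict):
        return {_key(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, frozenset):
        return "".join(sorted(obj))
    if hasattr(obj, "__dataclass_fields__"):
        return {
            k: _jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__
        }
    return obj


def _key(k):
    if isinstance(obj := k, frozenset):
        return "|".join(sorted(obj))
    return str(k)


def _write_tsv(path: Path, header: list[str], rows) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run every stage and return the consolidated report (also written to
    ``<out_dir>/report.json``).  Any stage failure aborts with a stage-
    tagged error; the MANIFEST lists the stages that completed."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "software": {"name": "chronodiv", "version": __version__},
        "config": _jsonable(asdict(config)),
        "stages": {},
    }
    manifest: list[str] = []
    stage = "read_trees"
    try:
        consensus = read_trees(config.tree_path, config.tree_format).trees[0]
        sample = None
        if config.sample_path:
            sample = read_trees(config.sample_path, config.sample_format)
        if config.outgroups:
            consensus = drop_taxa(consensus, config.outgroups)
            if sample is not None:
                sample = TreeSample(
                    trees=[drop_taxa(t, config.outgroups) for t in sample],
                    source=sample.source,
                )
        report["stages"]["read_trees"] = {
            "n_tips": consensus.n_tips,
            "crown_age_ma": consensus.crown_age,
            "n_sample_trees": len(sample) if sample else 0,
        }
        manifest.append(stage)

        stage = "gamma"
        bt = branching_times(consensus)
        gamma = gamma_statistic(bt)
        report["stages"]["gamma"] = _jsonable(gamma)
        manifest.append(stage)

        stage = "mccr"
        mccr = mccr_test(
            bt, n_total=max(config.n_total, bt.n), reps=config.mccr_reps,
            seed=config.seed,
        )
        mres = _jsonable(mccr)
        mres["null_gammas"] = {
            "mean": float(np.mean(mccr.null_gammas)),
            "sd": float(np.std(mccr.null_gammas, ddof=1)),
        }
        report["stages"]["mccr"] = mres
        _write_tsv(
            out / "mccr_null.tsv", ["gamma_null"],
            ([f"{v:.6f}"] for v in mccr.null_gammas),
        )
        manifest.append(stage)

        stage = "modelfit"
        comp = compare_models(bt, models=config.models)
        report["stages"]["modelfit"] = _jsonable(comp)
        manifest.append(stage)

        stage = "ltt"
        curve = ltt_curve(bt)
        _write_tsv(
            out / "ltt.tsv", ["age_ma", "lineages"],
            zip((f"{t:.6f}" for t in curve.times), curve.lineage_counts),
        )
        curves = []
        if sample is not None:
            k = min(config.mltt_k, len(sample))
            curves = mltt(sample, k=k, seed=config.seed)
            rows = []
            for i, c in enumerate(curves):
                rows += [(i, f"{t:.6f}", n) for t, n in zip(c.times, c.lineage_counts)]
            _write_tsv(out / "mltt.tsv", ["tree", "age_ma", "lineages"], rows)
        if config.figures:
            from .plots import plot_ltt

            plot_ltt([curve] + curves, str(out / "ltt.png"))
        report["stages"]["ltt"] = {"n_curves": 1 + len(curves)}
        manifest.append(stage)

        stage = "interval_rates"
        rates = interval_rates(bt, delta_t=config.delta_t)
        _write_tsv(
            out / "interval_rates.tsv",
            ["edge_old_ma", "edge_young_ma", "delta_n", "n_start", "rate", "rate_per_ma"],
            (
                (
                    f"{rates.bin_edges[i]:.6f}",
                    f"{rates.bin_edges[i+1]:.6f}",
                    rates.delta_n[i],
                    rates.n_start[i],
                    f"{rates.rate[i]:.6f}",
                    f"{rates.rate_per_ma[i]:.6f}",
                )
                for i in range(len(rates.delta_n))
            ),
        )
        if config.figures:
            from .plots import plot_interval_rates

            plot_interval_rates(rates, str(out / "interval_rates.png"))
        report["stages"]["interval_rates"] = _jsonable(rates)
        manifest.append(stage)

        stage = "branch_length_cdf"
        blcdf = branch_length_cdf(branch_lengths(consensus))
        report["stages"]["branch_length_cdf"] = _jsonable(blcdf)
        _write_tsv(
            out / "blcdf.tsv",
            ["class_edge_ma", "cumulative_freq", "constant_cdf", "variable_cdf"],
            zip(
                (f"{v:.6f}" for v in blcdf.class_edges),
                (f"{v:.6f}" for v in blcdf.cumulative_freq),
                (f"{v:.6f}" for v in blcdf.fitted_constant_cdf),
                (f"{v:.6f}" for v in blcdf.fitted_variable_cdf),
            ),
        )
        if config.figures:
            from .plots import plot_blcdf

            plot_blcdf(blcdf, str(out / "blcdf.png"))
        manifest.append(stage)

        if config.range_path:
            stage = "diva"
            ranges = read_range_table(config.range_path)
            recon = diva_optimize(consensus, ranges, max_areas=config.max_areas)
            report["stages"]["diva"] = {
                "min_cost": recon.min_cost,
                "root_ranges": _jsonable(recon.node_ranges[recon.root_clade]),
            }
            manifest.append(stage)

            if sample is not None:
                stage = "sdiva"
                summary = sdiva_summarize(
                    sample, ranges, max_areas=config.max_areas,
                    reference=consensus,
                )
                nodes = {}
                for clade, probs in summary.clade_probs.items():
                    key = "|".join(sorted(clade))
                    nodes[key] = {
                        "support": summary.clade_support[clade],
                        "probs": {
                            "".join(sorted(r)): p for r, p in probs.items()
                        },
                    }
                report["stages"]["sdiva"] = {
                    "n_trees": summary.n_trees,
                    "weighting": summary.weighting,
                    "nodes": nodes,
                }
                with open(out / "sdiva_nodes.json", "w") as fh:
                    json.dump(nodes, fh, indent=1, sort_keys=True)
                if config.figures:
                    from .plots import plot_node_pies

                    plot_node_pies(
                        consensus, summary, str(out / "node_pies.png")
                    )
                manifest.append(stage)
    except Exception as exc:
        (out / "MANIFEST").write_text(
            "\n".join(manifest + [f"FAILED at stage: {stage}"]) + "\n"
        )
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "MANIFEST").write_text("\n".join(manifest + ["complete"]) + "\n")
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    log.info("pipeline complete: %d stages -> %s", len(manifest), out)
    return report
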