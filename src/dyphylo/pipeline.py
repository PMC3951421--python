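"""End-to-end analysis pipeline: filter -> distances/network/scores ->
constrained vs unconstrained MCMC -> stepping-stone Bayes factor ->
consensus summaries -> structured report.

The constrained model forces the named ingroup (e.g. all non-Yeniseian
languages) to be monophyletic, modelling the "early split" dispersal
hypothesis; the unconstrained model leaves the placement free. A positive
log Bayes factor (unconstrained minus constrained) counts against the early
split.

Every stage draws its seed deterministically from the master seed and the
stage name, so any number in the report can be recomputed from the MANIFEST.
"""

from __future__ import annotations

import hashlib
import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .charmatrix import (
    CharacterMatrix,
    drop_taxa,
    filter_uninformative,
    read_nexus_characters,
    write_nexus_characters,
)
from .consensus import consensus_network, majority_consensus
from .distnet import (
    distance_matrix,
    neighbor_net,
    treelikeness,
    write_distances_nexus,
    write_splits_nexus,
)
from .likelihood import SubstModel
from .marginal import bayes_factor, harmonic_mean_logml, stepping_stone_logml
from .mcmc import Constraint, MCMCConfig, run_mcmc
from .trees import PhyloTree

__all__ = ["AnalysisConfig", "run_full_analysis", "exclusion_suite",
           "stage_seed", "validate_report"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 derived from the master seed."""
    h = hashlib.blake2s(
        f"{master_seed}:{stage}".encode(), digest_size=4
    ).digest()
    return int.from_bytes(h, "big") % (2**31)


@dataclass(frozen=True)
class AnalysisConfig:
    matrix_path: str
    out_dir: str
    constraint_taxa: frozenset[str] = frozenset()
    outgroup: str | None = None
    clock: str = "strict"
    n_generations: int = 2_000_000
    sample_every: int = 500
    burnin_fraction: float = 0.25
    ss_steps: int = 50
    ss_generations_per_step: int = 10_000
    ss_runs: int = 3
    exclusions: tuple[frozenset[str], ...] = ()
    pi1: float = 0.5
    alpha: float = 1.0
    ascertainment: str = "variable"
    master_seed: int = 0

    @classmethod
    def from_json(cls, path: str) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        raw["constraint_taxa"] = frozenset(raw.get("constraint_taxa", []))
        raw["exclusions"] = tuple(
            frozenset(x) for x in raw.get("exclusions", [])
        )
        return cls(**raw)


def _write(path: Path, text: str) -> None:
    path.write_text(text, encoding="utf-8")


def write_trees_nexus(trees: list[PhyloTree], names: list[str]) -> str:
    lines = ["#NEXUS", "", "BEGIN TREES;"]
    for name, t in zip(names, trees):
        lines.append(f"    TREE {name} = {t.to_newick()}")
    lines += ["END;", ""]
    return "\n".join(lines)


def _treelikeness_table(report) -> pd.DataFrame:
    rows = [
        {
            "taxon": t,
            "delta": report.per_taxon_delta[t],
            "q_residual": report.per_taxon_q[t],
        }
        for t in report.per_taxon_delta
    ]
    df = pd.DataFrame(rows)
    df["rank_by_delta"] = df["delta"].rank(method="min").astype(int)
    df["rank_by_q"] = df["q_residual"].rank(method="min").astype(int)
    return df.sort_values("delta").reset_index(drop=True)


def _mcmc_and_ss(
    m: CharacterMatrix,
    model: SubstModel,
    cfg: AnalysisConfig,
    constrained: bool,
    out: Path,
    manifest: dict,
) -> dict:
    label = "constrained" if constrained else "unconstrained"
    constraints = (
        (Constraint(cfg.constraint_taxa),) if constrained else ()
    )
    mcfg = MCMCConfig(
        n_generations=cfg.n_generations,
        sample_every=cfg.sample_every,
        burnin_fraction=cfg.burnin_fraction,
        clock=cfg.clock,
        constraints=constraints,
        outgroup=cfg.outgroup,
        seed=stage_seed(cfg.master_seed, f"mcmc:{label}"),
    )
    trace = run_mcmc(m, model, mcfg)
    _write(
        out / f"trace_{label}.trees.nex",
        write_trees_nexus(
            trace.trees, [f"gen_{g}" for g in trace.generations]
        ),
    )
    pd.DataFrame(
        {
            "generation": trace.generations,
            "logL": trace.log_likelihood,
            "logPrior": trace.log_prior,
            "pi1": trace.pi1,
            "alpha": trace.alpha,
            "clock_rate": trace.clock_rate,
        }
    ).to_csv(out / f"trace_{label}.tsv", sep="\t", index=False)
    hm = harmonic_mean_logml(trace)
    ss_cfg = MCMCConfig(
        n_generations=0,
        sample_every=1,
        burnin_fraction=0.0,
        clock=cfg.clock,
        constraints=constraints,
        outgroup=cfg.outgroup,
        seed=stage_seed(cfg.master_seed, f"ss:{label}"),
    )
    ss = stepping_stone_logml(
        m, model, ss_cfg,
        K=cfg.ss_steps,
        per_step_generations=cfg.ss_generations_per_step,
        n_runs=cfg.ss_runs,
    )
    manifest["stages"][f"mcmc:{label}"] = {"seed": mcfg.seed}
    manifest["stages"][f"ss:{label}"] = {"seeds": list(ss.seeds)}
    # consensus summaries from the retained sample
    retained = trace.retained_trees()
    cons = majority_consensus(retained, 0.5)
    _write(out / f"consensus_{label}.nwk", cons.to_newick())
    net = consensus_network(retained, 0.1)
    _write(out / f"consensus_network_{label}.nex", write_splits_nexus(net))
    return {
        "label": label,
        "trace": trace,
        "consensus": cons,
        "stepping_stone": {
            "method": ss.method,
            "log_ml": ss.log_ml,
            "per_run": list(ss.per_run),
            "K": ss.K,
            "seeds": list(ss.seeds),
        },
        "harmonic_mean": {
            "log_ml": hm.log_ml,
            "note": hm.note,
        },
        "_ss_obj": ss,
        "_hm_obj": hm,
    }


def run_full_analysis(cfg: AnalysisConfig) -> dict:
    """Run the complete analysis; returns the report dict (also written to
    ``report.json`` with the validation schema and a MANIFEST)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "master_seed": cfg.master_seed,
        "config": _config_dict(cfg),
        "version": __version__,
        "stages": {},
        "complete": False,
    }
    stage = "start"
    t0 = time.time()
    log_lines = [f"dyphylo {__version__} master_seed={cfg.master_seed}"]
    try:
        stage = "read"
        m = read_nexus_characters(cfg.matrix_path)
        stage = "filter"
        filtered, freport = filter_uninformative(m)
        _write(out / "filtered.nex", write_nexus_characters(filtered))
        pd.DataFrame(
            [
                {
                    "n_input": freport.n_input,
                    "n_excluded": freport.n_excluded,
                    "n_retained": freport.n_retained,
                }
            ]
        ).to_csv(out / "filter_report.tsv", sep="\t", index=False)
        log_lines.append(
            f"filter: {freport.n_input} -> {freport.n_retained} characters"
        )

        stage = "distances"
        dm = distance_matrix(filtered)
        _write(out / "distances.nex", write_distances_nexus(dm))
        scores = treelikeness(dm)
        _treelikeness_table(scores).to_csv(
            out / "treelikeness.tsv", sep="\t", index=False
        )
        stage = "neighbor_net"
        nnet = neighbor_net(dm)
        _write(out / "splits.nex", write_splits_nexus(nnet))
        log_lines.append(
            f"treelikeness: avg_delta={scores.avg_delta:.4f} "
            f"avg_q={scores.avg_q_residual:.4f}; "
            f"{nnet.n_splits} fitted splits"
        )

        model = SubstModel(
            pi1=cfg.pi1, alpha=cfg.alpha, ascertainment=cfg.ascertainment
        )
        stage = "mcmc:unconstrained"
        unc = _mcmc_and_ss(filtered, model, cfg, False, out, manifest)
        stage = "mcmc:constrained"
        con = _mcmc_and_ss(filtered, model, cfg, True, out, manifest)

        stage = "bayes_factor"
        bf = bayes_factor(
            unc["_ss_obj"], con["_ss_obj"], "unconstrained", "constrained"
        )
        log_lines.append(
            f"log BF (unconstrained - constrained) = {bf.log_bf:.3f} "
            f"[{bf.category}], favoring {bf.direction}"
        )

        report = {
            "seed": cfg.master_seed,
            "version": __version__,
            "filter": {
                "n_input": freport.n_input,
                "n_excluded": freport.n_excluded,
                "n_retained": freport.n_retained,
            },
            "treelikeness": {
                "avg_delta": scores.avg_delta,
                "avg_q_residual": scores.avg_q_residual,
            },
            "models": {
                r["label"]: {
                    "stepping_stone": r["stepping_stone"],
                    "harmonic_mean": r["harmonic_mean"],
                }
                for r in (unc, con)
            },
            "comparison": {
                "log_bf": bf.log_bf,
                "direction": bf.direction,
                "category": bf.category,
            },
            "settings": {
                "clock": cfg.clock,
                "n_generations": cfg.n_generations,
                "sample_every": cfg.sample_every,
                "burnin_fraction": cfg.burnin_fraction,
                "ss_steps": cfg.ss_steps,
                "ss_runs": cfg.ss_runs,
                "ascertainment": cfg.ascertainment,
            },
        }
        validate_report(report)
        _write(out / "report.json", json.dumps(report, indent=2))
        _write(out / "report.schema.json", json.dumps(REPORT_SCHEMA, indent=2))
        manifest["complete"] = True
        return report
    except Exception as exc:
        log_lines.append(f"FAILED at stage {stage}: {exc}")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        manifest["elapsed_s"] = round(time.time() - t0, 3)
        _write(out / "MANIFEST.json", json.dumps(manifest, indent=2))
        _write(out / "log.txt", "\n".join(log_lines) + "\n")


def exclusion_suite(
    cfg: AnalysisConfig, drop_sets: list[frozenset[str]]
) -> dict:
    """Distance/network scores recomputed after excluding each taxon set.

    Reports per-taxon delta and Q-residual shifts relative to the base
    matrix (surviving taxa only).
    """
    m = read_nexus_characters(cfg.matrix_path)
    base_filtered, _ = filter_uninformative(m)
    base_scores = treelikeness(distance_matrix(base_filtered))
    out = {"base": base_scores, "exclusions": {}}
    for drop in drop_sets:
        key = ",".join(sorted(drop)) if drop else "(none)"
        sub = drop_taxa(m, set(drop))
        sub_filtered, _ = filter_uninformative(sub)
        scores = treelikeness(distance_matrix(sub_filtered))
        shifts = {
            t: {
                "delta": scores.per_taxon_delta[t] - base_scores.per_taxon_delta[t],
                "q_residual": scores.per_taxon_q[t] - base_scores.per_taxon_q[t],
            }
            for t in scores.per_taxon_delta
        }
        out["exclusions"][key] = {"scores": scores, "shifts": shifts}
    return out


# ---------------------------------------------------------------------------
# report schema
# ---------------------------------------------------------------------------

REPORT_SCHEMA: dict = {
    "$schema": "https://json-schema.org/draft/2020-12/schema",
    "title": "dyphylo analysis report",
    "type": "object",
    "required": [
        "seed", "version", "filter", "treelikeness", "models",
        "comparison", "settings",
    ],
    "properties": {
        "seed": {"type": "integer"},
        "version": {"type": "string"},
        "filter": {
            "type": "object",
            "required": ["n_input", "n_excluded", "n_retained"],
            "properties": {
                "n_input": {"type": "integer"},
                "n_excluded": {"type": "integer"},
                "n_retained": {"type": "integer"},
            },
        },
        "treelikeness": {
            "type": "object",
            "required": ["avg_delta", "avg_q_residual"],
            "properties": {
                "avg_delta": {"type": "number"},
                "avg_q_residual": {"type": "number"},
            },
        },
        "models": {"type": "object"},
        "comparison": {
            "type": "object",
            "required": ["log_bf", "direction", "category"],
            "properties": {
                "log_bf": {"type": "number"},
                "direction": {"type": "string"},
                "category": {"type": "string"},
            },
        },
        "settings": {"type": "object"},
    },
}

_TYPES = {
    "object": dict,
    "integer": int,
    "number": (int, float),
    "string": str,
    "array": list,
}


def validate_report(report: dict, schema: dict | None = None) -> None:
    """Check the report against the shipped schema (types + required keys).

    Raises ValueError on the first violation.
    """
    schema = REPORT_SCHEMA if schema is None else schema

    def check(obj, sch, path):
        expected = sch.get("type")
        if expected and not isinstance(obj, _TYPES[expected]):
            raise ValueError(
                f"{path}: expected {expected}, got {type(obj).__name__}"
            )
        if isinstance(obj, bool) and expected in ("integer", "number"):
            raise ValueError(f"{path}: boolean is not a number")
        if expected == "object":
            for key in sch.get("required", []):
                if key not in obj:
                    raise ValueError(f"{path}: missing required key {key!r}")
            for key, sub in sch.get("properties", {}).items():
                if key in obj:
                    check(obj[key], sub, f"{path}.{key}")

    check(report, schema, "report")


def _config_dict(cfg: AnalysisConfig) -> dict:
    return {
        "matrix_path": cfg.matrix_path,
        "out_dir": cfg.out_dir,
        "constraint_taxa": sorted(cfg.constraint_taxa),
        "outgroup": cfg.outgroup,
        "clock": cfg.clock,
        "n_generations": cfg.n_generations,
        "sample_every": cfg.sample_every,
        "burnin_fraction": cfg.burnin_fraction,
        "ss_steps": cfg.ss_steps,
        "ss_generations_per_step": cfg.ss_generations_per_step,
        "ss_runs": cfg.ss_runs,
        "exclusions": [sorted(x) for x in cfg.exclusions],
        "pi1": cfg.pi1,
        "alpha": cfg.alpha,
        "ascertainment": cfg.ascertainment,
        "master_seed": cfg.master_seed,
    }
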