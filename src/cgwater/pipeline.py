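"""Configuration-driven studies: evidence sweeps over a model grid, ranked
comparison tables, and report generation.

A study config names a grid of models (structure x mapping), a QoI source
(the packaged experimental table, a CSV file, or a synthetic suite), a
forward backend (closed-form surrogate or the bundled MD engine) and
sampler settings.  ``run_study`` computes, for every model: the posterior,
the evidence report (log-evidence with its fit/information-gain split), the
MAP parameters and MAP-predicted QoI (mean and SD of 5 replicate forward
evaluations), then aggregates rankings per comparable QoI set.  All outputs
are JSON-first; the Markdown report only re-formats JSON fields.

Two presets are bundled: ``surrogate-full`` (closed-form backend, the
quantitative desk-scale suite) and ``md-reduced`` (MD backend at
desk-scale budgets; qualitative only).  Production-scale budgets are
encoded but gated behind an explicit ``cluster`` flag.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import units
from .engine.forward import MDForward, default_budget, forward_model
from .inference import (
    QoIDataset,
    evidence_decomposition,
    make_log_likelihood,
    map_estimate,
    read_qoi_csv,
    sample_posterior,
)
from .model_zoo import build_model, default_priors
from .selection import CostTable, rank_models
from .synthetic import SurrogateForward, load_experimental_qoi, make_benchmark_suite

__all__ = ["StudyConfig", "run_study", "write_report", "PRESETS"]


PRESETS = {
    "surrogate-full": {
        "backend": "surrogate",
        "models": [
            "1S,4", "2S,4", "3S,4", "3S*,4", "2SF,4", "3SF,4", "3SF*,4",
        ],
        "sampler": {"n_samples": 1000, "n_runs": 3},
    },
    "md-reduced": {
        "backend": "micro_md",
        "models": ["1S,4"],
        "sampler": {"n_samples": 16, "n_runs": 1, "n_mcmc_steps": 2},
        "budget": {
            "n_entities": 64,
            "npt_steps": 1500,
            "nvt_steps": 2000,
            "slab_steps": 1500,
        },
    },
}

# Production-scale budget (5 nm box, ~10 ns): only sensible on a cluster.
CLUSTER_BUDGET = {
    "n_entities": 1000,
    "npt_steps": 1_250_000,
    "nvt_steps": 1_250_000,
    "slab_steps": 1_250_000,
    "sample_every": 10,
    "viscosity_sample_every": 2,
}


@dataclass
class StudyConfig:
    """Declarative description of one study run."""

    models: list = field(default_factory=lambda: ["1S,4"])
    qoi_source: dict = field(default_factory=lambda: {"kind": "fixture"})
    backend: str = "surrogate"
    temperature: float = 298.0
    sampler: dict = field(default_factory=dict)
    budget: dict = field(default_factory=dict)
    costs: Optional[dict] = None        # label -> speedup
    seed: int = 0
    output_dir: str = "study_out"
    cluster: bool = False

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "StudyConfig":
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}")
        kw = {k: v for k, v in PRESETS[name].items()}
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def from_yaml(cls, text: str) -> "StudyConfig":
        data = yaml.safe_load(text) or {}
        preset = data.pop("preset", None)
        if preset:
            return cls.from_preset(preset, **data)
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def _parse_model_label(label):
    if isinstance(label, (list, tuple)):
        structure, mapping = label
    else:
        structure, mapping = label.rsplit(",", 1)
    return structure, int(mapping)


def _load_datasets(cfg: StudyConfig):
    src = dict(cfg.qoi_source)
    kind = src.pop("kind", "fixture")
    if kind == "fixture":
        datasets = load_experimental_qoi()
    elif kind == "csv":
        datasets = read_qoi_csv(src["path"])
    elif kind == "synthetic":
        src.setdefault("seed", cfg.seed)
        suite = make_benchmark_suite(src.pop("suite_kind", "common_truth"), **src)
        datasets = suite.datasets
    else:
        raise ValueError(f"unknown QoI source kind {kind!r}")
    by_t = {ds.temperature: ds for ds in datasets}
    if cfg.temperature not in by_t:
        raise ValueError(
            f"no dataset at {cfg.temperature} K (have {sorted(by_t)})"
        )
    return by_t[cfg.temperature]


def _restrict(ds: QoIDataset, labels) -> QoIDataset:
    keep = [i for i, l in enumerate(ds.labels) if l in labels]
    return QoIDataset(
        labels=[ds.labels[i] for i in keep],
        values=ds.values[keep],
        temperature=ds.temperature,
        units={ds.labels[i]: ds.units.get(ds.labels[i], "") for i in keep},
    )


def run_study(cfg: StudyConfig) -> dict:
    """Execute the study; returns the report dict (also written to disk).

    Failures of individual models are recorded and the study continues;
    the report's ``status`` is 'partial' if any model failed.
    """
    t_start = time.time()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset = _load_datasets(cfg)
    budget = dict(default_budget())
    budget.update(CLUSTER_BUDGET if cfg.cluster else {})
    budget.update(cfg.budget or {})

    model_entries = []
    failures = []
    seeds = np.random.SeedSequence(cfg.seed).spawn(len(cfg.models))
    for label, ss in zip(cfg.models, seeds):
        seed = int(ss.generate_state(1)[0] % (2**31))
        try:
            structure, mapping = _parse_model_label(label)
            entry = _run_one_model(
                structure, mapping, dataset, cfg, budget, seed
            )
            model_entries.append(entry)
        except Exception as exc:  # noqa: BLE001 - study must continue
            failures.append({"label": str(label), "error": str(exc)})

    # rankings per comparable QoI set
    rankings = []
    by_set = {}
    for e in model_entries:
        by_set.setdefault(tuple(e["qoi_set"]), []).append(e)
    for qoi_set, entries in sorted(by_set.items()):
        log_es = {e["label"]: e["evidence"]["log_evidence"] for e in entries}
        ses = {e["label"]: e["log_evidence_se"] for e in entries}
        costs = CostTable(cfg.costs) if cfg.costs else None
        criterion = "expected_utility" if costs else "evidence"
        try:
            ranking = rank_models(
                log_es, costs=costs, criterion=criterion,
                log_evidence_se=ses, qoi_set=qoi_set,
            )
        except KeyError:
            ranking = rank_models(
                log_es, criterion="evidence", log_evidence_se=ses,
                qoi_set=qoi_set,
            )
        rankings.append(ranking.to_dict())

    report = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "temperature_K": cfg.temperature,
        "backend": cfg.backend,
        "sampler": {**{"defaults": "package"}, **(cfg.sampler or {})},
        "fidelity": (
            "cluster budgets" if cfg.cluster else
            "desk-scale budgets (qualitative for the MD backend)"
        ),
        "status": "partial" if failures else "ok",
        "models": model_entries,
        "failures": failures,
        "rankings": rankings,
        "wall_time_s": round(time.time() - t_start, 3),
    }
    write_report(report, out)
    (out / "config.yaml").write_text(cfg.to_yaml())
    return report


def _run_one_model(structure, mapping, dataset, cfg, budget, seed):
    spec = build_model(structure, mapping)
    prior = default_priors(spec)
    if cfg.backend == "surrogate":
        forward = SurrogateForward(spec, prior)
        labels = forward.labels
    elif cfg.backend == "micro_md":
        forward = MDForward(spec, budget=budget, seed=seed)
        labels = forward.labels
    else:
        raise ValueError(f"unknown backend {cfg.backend!r}")

    ds = _restrict(dataset, labels)
    ll = make_log_likelihood(forward, ds)
    ens = sample_posterior(
        prior, ll, sampler_cfg=cfg.sampler or None, seed=seed,
        names=prior.names,
    )
    report = evidence_decomposition(ens, prior)
    phi_map = map_estimate(ens, prior)

    # MAP-predicted QoI: mean/SD over 5 replicate forward evaluations
    rep_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed + 1).spawn(5)
    ]
    preds = []
    for rs in rep_seeds:
        if cfg.backend == "surrogate":
            noisy = SurrogateForward(spec, prior, jitter=0.02)
            F = noisy(phi_map.phi_c, ds.temperature,
                      rng=np.random.default_rng(rs))
        else:
            ov = forward_model(
                spec, phi_map.phi_c, ds.temperature, budget=budget, seed=rs
            )
            F = ov.as_array(labels)
        preds.append(F)
    preds = np.asarray(preds)

    return {
        "label": spec.label,
        "structure": structure,
        "mapping": mapping,
        "seed": seed,
        "qoi_set": list(ds.labels),
        "n_data": ds.n,
        "evidence": report.to_dict(),
        "log_evidence_se": ens.log_evidence_se,
        "map_parameters": {
            n: float(v)
            for n, v in zip(ens.names, phi_map.full)
        },
        "map_predicted_qoi": {
            "labels": list(ds.labels),
            "mean": preds.mean(axis=0).tolist(),
            "sd": preds.std(axis=0, ddof=1).tolist(),
            "n_replicates": len(preds),
        },
        "data": {"labels": list(ds.labels), "values": ds.values.tolist()},
        "sampler_diagnostics": {
            "stages": ens.diagnostics["stages"],
        },
    }


def write_report(report: dict, out_dir) -> None:
    """Write the JSON report and its Markdown twin.

    Every number in the Markdown is read back from the JSON dict, so the
    two can never disagree.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "study.json").write_text(json.dumps(report, indent=2))

    lines = ["# Study report", ""]
    lines.append(f"- config hash: `{report['config_hash']}`")
    lines.append(f"- seed: {report['seed']}")
    lines.append(f"- backend: {report['backend']}")
    lines.append(f"- temperature: {report['temperature_K']} K")
    lines.append(f"- fidelity: {report['fidelity']}")
    lines.append(f"- status: {report['status']}")
    lines.append("")
    lines.append("## Model evidences")
    lines.append("")
    lines.append("| model | logE | +-SE | expected fit | info gain |")
    lines.append("|---|---|---|---|---|")
    for e in sorted(
        report["models"], key=lambda m: -m["evidence"]["log_evidence"]
    ):
        ev = e["evidence"]
        lines.append(
            f"| {e['label']} | {ev['log_evidence']:.3f} | "
            f"{e['log_evidence_se']:.3f} | {ev['expected_fit']:.3f} | "
            f"{ev['information_gain']:.3f} |"
        )
    for rk in report["rankings"]:
        lines.append("")
        lines.append(f"## Ranking ({rk['criterion']}; QoI: "
                     f"{', '.join(rk['qoi_set'])})")
        lines.append("")
        has_u = any("expected_utility" in e for e in rk["entries"])
        if has_u:
            lines.append("| rank | model | logE | p(M|d) | u | U |")
            lines.append("|---|---|---|---|---|---|")
        else:
            lines.append("| rank | model | logE | p(M|d) |")
            lines.append("|---|---|---|---|")
        for i, e in enumerate(rk["entries"], 1):
            row = (
                f"| {i} | {e['label']} | {e['log_evidence']:.3f} | "
                f"{e['posterior_prob']:.4f} |"
            )
            if has_u:
                row += (
                    f" {e.get('utility', float('nan')):.3f} | "
                    f"{e.get('expected_utility', float('nan')):.4f} |"
                )
            lines.append(row)
    if report["failures"]:
        lines.append("")
        lines.append("## Failures")
        for f in report["failures"]:
            lines.append(f"- {f['label']}: {f['error']}")
    (out / "study.md").write_text("\n".join(lines) + "\n")
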