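"""Model posterior probabilities, expected utility and rankings.

Given log-evidences ln p(d|M_i) and prior model probabilities p(M_i), the
model posterior is p(M_i|d) ∝ p(d|M_i) p(M_i) (computed overflow-safely in
log space).  The accuracy/efficiency trade-off is scored by the expected
utility U(M_i; d) = p(M_i|d) u(M_i) with u the decimal logarithm of the
computational speedup over the atomistic baseline.  Speedups are
user-supplied: wall-clock is hardware-dependent and is not measured by this
package.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "CostTable",
    "ModelRanking",
    "model_posterior",
    "expected_utility",
    "rank_models",
    "PUBLISHED_M4_LOG_EVIDENCES",
]

# Published log-evidences for the six mapping-4 models (rigid and flexible),
# usable as inputs to the selection arithmetic.
PUBLISHED_M4_LOG_EVIDENCES = {
    "2S,4": -2.28,
    "2SF,4": -2.25,
    "3S,4": -2.23,
    "3SF,4": -2.37,
    "3S*,4": -2.05,
    "3SF*,4": -2.54,
}


@dataclass
class CostTable:
    """Per-model computational speedup relative to the atomistic baseline."""

    speedups: dict
    provenance: str = "user-supplied"

    def __post_init__(self):
        for label, s in self.speedups.items():
            if s <= 0:
                raise ValueError(f"speedup for {label!r} must be positive")

    def utility(self, label: str) -> float:
        if label not in self.speedups:
            raise KeyError(f"no cost entry for model {label!r}")
        return math.log10(self.speedups[label])


@dataclass
class ModelRanking:
    """Ranked model comparison; rows sorted by the chosen criterion."""

    criterion: str
    entries: list                      # dicts per model, in rank order
    qoi_set: Optional[tuple] = None    # QoI labels the evidences refer to

    def labels(self):
        return [e["label"] for e in self.entries]

    def to_dict(self) -> dict:
        return {
            "criterion": self.criterion,
            "qoi_set": list(self.qoi_set) if self.qoi_set else None,
            "entries": self.entries,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_markdown(self) -> str:
        cols = ["rank", "label", "log_evidence", "posterior_prob"]
        has_u = any("expected_utility" in e for e in self.entries)
        if has_u:
            cols += ["utility", "expected_utility"]
        lines = [
            "| " + " | ".join(cols) + " |",
            "|" + "|".join("---" for _ in cols) + "|",
        ]
        for i, e in enumerate(self.entries, 1):
            row = [str(i), e["label"], f"{e['log_evidence']:.4g}",
                   f"{e['posterior_prob']:.4g}"]
            if has_u:
                row += [
                    f"{e.get('utility', float('nan')):.4g}",
                    f"{e.get('expected_utility', float('nan')):.4g}",
                ]
            lines.append("| " + " | ".join(row) + " |")
        if self.qoi_set:
            lines.append("")
            lines.append(f"QoI set: {', '.join(self.qoi_set)}")
        return "\n".join(lines)


def model_posterior(log_evidences: dict, model_priors: Optional[dict] = None) -> dict:
    """p(M_i|d) from log-evidences and prior model probabilities.

    Computed by max-subtraction in log space; adding any constant to all
    log-evidences leaves the result unchanged.  With ``model_priors=None``
    all models are equally probable a priori.
    """
    if not log_evidences:
        raise ValueError("no models given")
    labels = sorted(log_evidences)
    if model_priors is None:
        log_prior = {l: 0.0 for l in labels}
    else:
        pr = np.array([model_priors[l] for l in labels], dtype=float)
        if np.any(pr < 0) or not np.any(pr > 0):
            raise ValueError("model priors must be nonnegative, one positive")
        with np.errstate(divide="ignore"):
            lp = np.log(pr)
        log_prior = dict(zip(labels, lp))
    scores = np.array([log_evidences[l] + log_prior[l] for l in labels])
    m = scores.max()
    w = np.exp(scores - m)
    w /= w.sum()
    return dict(zip(labels, w))


def expected_utility(posteriors: dict, costs: CostTable) -> dict:
    """U(M_i; d) = p(M_i|d) * log10(speedup_i) per model."""
    return {
        label: p * costs.utility(label) for label, p in posteriors.items()
    }


def rank_models(
    log_evidences: dict,
    model_priors: Optional[dict] = None,
    costs: Optional[CostTable] = None,
    criterion: str = "evidence",
    log_evidence_se: Optional[dict] = None,
    qoi_set=None,
) -> ModelRanking:
    """Deterministic ranked comparison of models.

    ``criterion`` is 'evidence' or 'expected_utility'.  Exact ties break
    lexicographically by label.  ``qoi_set`` annotates which QoI labels the
    evidences were computed against; rankings are only meaningful within a
    fixed QoI set (chargeless and charged models are not comparable when
    the dielectric constant is among the QoI).
    """
    if criterion not in ("evidence", "expected_utility"):
        raise ValueError(f"unknown ranking criterion {criterion!r}")
    if not log_evidences:
        raise ValueError("no models given")
    if criterion == "expected_utility" and costs is None:
        raise ValueError("expected_utility ranking needs a CostTable")
    post = model_posterior(log_evidences, model_priors)
    utils = expected_utility(post, costs) if costs is not None else {}

    entries = []
    for label in sorted(log_evidences):
        e = {
            "label": label,
            "log_evidence": float(log_evidences[label]),
            "posterior_prob": float(post[label]),
        }
        if log_evidence_se and label in log_evidence_se:
            e["log_evidence_se"] = float(log_evidence_se[label])
        if costs is not None:
            e["utility"] = float(costs.utility(label))
            e["expected_utility"] = float(utils[label])
        entries.append(e)

    key = "log_evidence" if criterion == "evidence" else "expected_utility"
    entries.sort(key=lambda e: (-e[key], e["label"]))
    return ModelRanking(
        criterion=criterion,
        entries=entries,
        qoi_set=tuple(qoi_set) if qoi_set else None,
    )
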