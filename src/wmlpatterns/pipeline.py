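"""End-to-end orchestration and the simulation recovery harness.

``run_pipeline`` composes the stages in analysis order — descriptors →
consensus tree → pattern assignment → survival records → hazard models — on
either a cohort file or a generator configuration, writes every intermediate
next to the report so each reported number is recomputable, and returns a
:class:`PipelineReport`.

``threshold_recovery_study`` and ``hazard_recovery_study`` re-run the
discovery (or the fully adjusted Cox model with truth-defined patterns) on
many independently seeded synthetic cohorts and summarize how well the
planted thresholds / log hazard ratio are recovered.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import survival as surv
from .cohort import Subject, read_cohort, write_cohort
from .features import feature_frame, write_features
from .simulate import GeneratorConfig, generate_cohort, write_truth
from .tree import (
    ConsensusTree,
    assign_patterns,
    classification_metrics,
    consensus_tree,
)

log = logging.getLogger("wmlpatterns")

__all__ = [
    "PipelineReport",
    "event_labels",
    "hazard_recovery_study",
    "render_report",
    "run_pipeline",
    "threshold_recovery_study",
    "truth_consensus",
]


def event_labels(subjects: Sequence[Subject]) -> pd.Series:
    """Tree outcome: 1 if the subject progressed to MCI/dementia at any
    follow-up visit, 0 otherwise (censored subjects count as healthy)."""
    return pd.Series(
        {s.subject_id: int(s.first_event() is not None) for s in subjects}, name="event"
    )


def truth_consensus(config: GeneratorConfig) -> ConsensusTree:
    """A depth-2 tree holding the generator's planted thresholds; used to
    assign patterns by the latent truth in recovery studies."""
    return ConsensusTree(
        k=0,
        root_feature="total_wml",
        root_threshold=config.true_total_threshold,
        second_feature="temporal_wmlr",
        second_threshold=config.true_temporal_wmlr_threshold,
    )


@dataclass
class PipelineReport:
    """Everything the analysis produced, plus run metadata."""

    seed: int
    config_hash: str
    n_subjects: int
    consensus: ConsensusTree
    pattern_counts: dict[int, int]
    metrics: Optional[dict]
    person_years: float
    incidence_overall: float
    incidence_mci: float
    incidence_dementia: float
    cox_fits: dict[int, surv.CoxFit] = field(default_factory=dict)
    truth_comparison: Optional[dict] = None

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "n_subjects": self.n_subjects,
            "consensus": self.consensus.to_dict(),
            "pattern_counts": {str(k): v for k, v in self.pattern_counts.items()},
            "metrics": self.metrics,
            "person_years": self.person_years,
            "incidence_overall": self.incidence_overall,
            "incidence_mci": self.incidence_mci,
            "incidence_dementia": self.incidence_dementia,
            "cox_fits": {str(m): f.to_dict() for m, f in self.cox_fits.items()},
            "truth_comparison": self.truth_comparison,
        }


def _config_hash(obj) -> str:
    blob = json.dumps(repr(obj), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(
    *,
    cohort_path: Optional[Path | str] = None,
    generator_config: Optional[GeneratorConfig] = None,
    outdir: Path | str,
    seed: int = 0,
    k: int = 10,
    min_leaf: int = 6,
    reference_pattern: int = 1,
    models: Sequence[int] = (1, 2, 3, 4, 5),
) -> PipelineReport:
    """Run the full analysis and write all intermediates into ``outdir``.

    Exactly one of ``cohort_path`` / ``generator_config`` must be given.  The
    seed drives both the synthetic cohort (when generating) and the
    cross-validation fold partition.
    """
    if (cohort_path is None) == (generator_config is None):
        raise ValueError("give exactly one of cohort_path or generator_config")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if generator_config is not None:
        log.info("generating synthetic cohort (n=%d, seed=%d)", generator_config.n_subjects, seed)
        sample = generate_cohort(generator_config, seed=seed)
        subjects = sample.subjects
        write_cohort(subjects, outdir / "cohort.csv")
        write_truth(sample.truth, outdir / "truth.csv")
        truth = sample.truth
        config_hash = _config_hash(generator_config)
    else:
        log.info("reading cohort from %s", cohort_path)
        subjects = read_cohort(cohort_path)
        truth = None
        config_hash = _config_hash(str(cohort_path))

    feats = feature_frame(subjects)
    write_features(feats, outdir / "features.csv")
    labels = event_labels(subjects).loc[feats.index]

    log.info("fitting %d-fold consensus tree (min_leaf=%d, seed=%d)", k, min_leaf, seed)
    consensus = consensus_tree(feats, labels, k=k, min_leaf=min_leaf, seed=seed)
    consensus.save(outdir / "consensus.json")

    metrics = None
    pattern_counts: dict[int, int] = {}
    if consensus.stable:
        patterns = assign_patterns(feats, consensus)
        patterns.to_frame().to_csv(outdir / "patterns.csv")
        pattern_counts = {p: int((patterns == p).sum()) for p in (1, 2, 3)}
        metrics = classification_metrics(patterns == 3, labels)
    else:
        log.warning("consensus unstable (root votes %s); patterns not assigned", consensus.root_votes)
        patterns = pd.Series(1, index=feats.index, name="pattern")

    records = surv.build_survival_records(subjects, patterns.to_dict())
    surv.write_records(records, outdir / "records.csv")
    py = surv.person_years(records)
    report = PipelineReport(
        seed=seed,
        config_hash=config_hash,
        n_subjects=len(subjects),
        consensus=consensus,
        pattern_counts=pattern_counts,
        metrics=metrics,
        person_years=py,
        incidence_overall=surv.incidence_rate(records),
        incidence_mci=surv.incidence_rate(records, "mci"),
        incidence_dementia=surv.incidence_rate(records, "dementia"),
    )

    if consensus.stable:
        for m in models:
            try:
                fit = surv.cox_delayed_entry(records, m, reference_pattern=reference_pattern)
            except Exception as e:  # propagate with stage name
                raise RuntimeError(f"cox model {m} failed: {e}") from e
            report.cox_fits[m] = fit
        with open(outdir / "fits.json", "w", encoding="utf-8") as fh:
            json.dump({str(m): f.to_dict() for m, f in report.cox_fits.items()}, fh, indent=2)

    if truth is not None and consensus.stable:
        true_pat = truth.set_index("subject_id")["true_pattern"]
        agreement = float((patterns.loc[true_pat.index] == true_pat).mean())
        report.truth_comparison = {
            "true_total_threshold": generator_config.true_total_threshold,
            "recovered_root_threshold": consensus.root_threshold,
            "true_temporal_wmlr_threshold": generator_config.true_temporal_wmlr_threshold,
            "recovered_second_threshold": consensus.second_threshold,
            "root_feature": consensus.root_feature,
            "second_feature": consensus.second_feature,
            "pattern_agreement": agreement,
        }

    (outdir / "report.txt").write_text(render_report(report), encoding="utf-8")
    return report


def render_report(r: PipelineReport) -> str:
    """Human-readable report body (no timestamps, so reruns are byte-stable)."""
    lines = [
        "WML pattern analysis report",
        "===========================",
        f"seed: {r.seed}   config: {r.config_hash}   n: {r.n_subjects}",
        "",
        "Consensus tree",
        "--------------",
    ]
    c = r.consensus
    if c.stable:
        lines += [
            f"root:   {c.root_feature} >= {c.root_threshold:g}  (votes {c.root_votes})",
            f"second: {c.second_feature} >= {c.second_threshold:g}  (votes {c.second_votes})",
            "patterns: "
            + "; ".join(f"{p}: {d}" for p, d in c.pattern_definitions().items()),
            "pattern counts: "
            + ", ".join(f"{p}: {n}" for p, n in sorted(r.pattern_counts.items())),
        ]
    else:
        lines += [f"UNSTABLE consensus (root votes {c.root_votes})"]
    if r.metrics:
        m = r.metrics

        def f(v):
            return "NA" if v is None else f"{v:.1f}%"

        lines += [
            "",
            "Pattern 3 vs observed progression (resubstitution)",
            f"sensitivity {f(m['sensitivity'])}  specificity {f(m['specificity'])}  "
            f"PPV {f(m['ppv'])}  NPV {f(m['npv'])}",
            f"2x2: TP={m['tp']} FN={m['fn']} FP={m['fp']} TN={m['tn']}",
        ]
    lines += [
        "",
        "Follow-up",
        "---------",
        f"person-years: {r.person_years:.1f}",
        f"incidence (per 1000 py): overall {r.incidence_overall:.1f}, "
        f"MCI {r.incidence_mci:.1f}, dementia {r.incidence_dementia:.1f}",
    ]
    if r.cox_fits:
        lines += ["", "Hazard ratios", "-------------"]
        for m, fit in sorted(r.cox_fits.items()):
            parts = []
            for p in (1, 2, 3):
                name = f"pattern_{p}"
                if name in fit.summary.index:
                    hr, lo, hi = fit.hr(name)
                    parts.append(f"pattern {p} vs {fit.reference_pattern}: "
                                 f"{hr:.2f} ({lo:.2f}-{hi:.2f})")
            lines.append(f"model {m} (n={fit.n}, events={fit.n_events}): " + "; ".join(parts))
    if r.truth_comparison:
        t = r.truth_comparison
        lines += [
            "",
            "Truth vs recovered",
            "------------------",
            f"root: {t['root_feature']} at {t['recovered_root_threshold']:g} "
            f"(true total threshold {t['true_total_threshold']:g} ml)",
            f"second: {t['second_feature']} at {t['recovered_second_threshold']:g} "
            f"(true temporal WMLr threshold {t['true_temporal_wmlr_threshold']:g}%)",
            f"pattern agreement: {100 * t['pattern_agreement']:.1f}%",
        ]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Recovery studies
# ---------------------------------------------------------------------------


def _replicate_seeds(seed: int, n: int) -> np.ndarray:
    """Independent per-replicate seeds derived from one master seed."""
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def threshold_recovery_study(
    config: GeneratorConfig,
    n_replicates: int,
    seed: int = 0,
    *,
    k: int = 10,
    min_leaf: int = 6,
) -> tuple[pd.DataFrame, dict]:
    """Re-run the consensus-tree discovery on independently seeded cohorts.

    Returns the per-replicate table (recovered root/second descriptor and
    threshold) and a summary: how often both planted descriptors were
    recovered, and the mean recovered thresholds among the replicates that
    picked the planted descriptor at each position.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    rows = []
    for rep_seed in _replicate_seeds(seed, n_replicates):
        sample = generate_cohort(config, seed=int(rep_seed))
        feats = feature_frame(sample.subjects)
        labels = event_labels(sample.subjects).loc[feats.index]
        c = consensus_tree(feats, labels, k=k, min_leaf=min_leaf, seed=int(rep_seed))
        rows.append(
            {
                "seed": int(rep_seed),
                "root_feature": c.root_feature,
                "root_threshold": c.root_threshold,
                "second_feature": c.second_feature,
                "second_threshold": c.second_threshold,
                "n_events": int(labels.sum()),
            }
        )
    df = pd.DataFrame(rows)
    root_ok = df["root_feature"] == "total_wml"
    second_ok = root_ok & (df["second_feature"] == "temporal_wmlr")
    summary = {
        "n_replicates": n_replicates,
        "root_recovery_frequency": float(root_ok.mean()),
        "both_recovery_frequency": float(second_ok.mean()),
        "mean_root_threshold": float(df.loc[root_ok, "root_threshold"].mean()),
        "sd_root_threshold": float(df.loc[root_ok, "root_threshold"].std()),
        "mean_second_threshold": float(df.loc[second_ok, "second_threshold"].mean()),
        "sd_second_threshold": float(df.loc[second_ok, "second_threshold"].std()),
        "true_total_threshold": config.true_total_threshold,
        "true_temporal_wmlr_threshold": config.true_temporal_wmlr_threshold,
    }
    return df, summary


def hazard_recovery_study(
    config: GeneratorConfig,
    n_replicates: int,
    seed: int = 0,
    *,
    model: int = 5,
    reference_pattern: int = 1,
    use_true_patterns: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Re-fit the adjusted delayed-entry Cox model on independently seeded
    cohorts and summarize the estimated pattern-3 hazard ratio.

    By default patterns are assigned from the generator's planted thresholds
    (isolating the Cox stage from tree estimation error); set
    ``use_true_patterns=False`` to assign from a freshly fitted consensus.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    rows = []
    for rep_seed in _replicate_seeds(seed, n_replicates):
        sample = generate_cohort(config, seed=int(rep_seed))
        feats = feature_frame(sample.subjects)
        if use_true_patterns:
            consensus = truth_consensus(config)
        else:
            labels = event_labels(sample.subjects).loc[feats.index]
            consensus = consensus_tree(feats, labels, seed=int(rep_seed))
            if not consensus.stable:
                continue
        patterns = assign_patterns(feats, consensus)
        records = surv.build_survival_records(sample.subjects, patterns.to_dict())
        fit = surv.cox_delayed_entry(records, model, reference_pattern=reference_pattern)
        name = "pattern_3" if reference_pattern != 3 else "pattern_1"
        rows.append(
            {
                "seed": int(rep_seed),
                "log_hr": fit.coef(name),
                "hr": fit.hr(name)[0],
                "n": fit.n,
                "n_events": fit.n_events,
            }
        )
    df = pd.DataFrame(rows)
    mean_log = float(df["log_hr"].mean())
    summary = {
        "n_replicates": int(len(df)),
        "geometric_mean_hr": float(math.exp(mean_log)),
        "mean_log_hr": mean_log,
        "sd_log_hr": float(df["log_hr"].std()),
        "true_hr": float(math.exp(config.log_hazard_pattern3)),
        "mean_n_events": float(df["n_events"].mean()),
    }
    return df, summary
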