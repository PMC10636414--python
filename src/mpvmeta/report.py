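"""End-to-end pipeline: effects -> pooling -> subgroups -> meta-regression ->
bias diagnostics -> sensitivity, with machine-readable JSON/TSV output.

Every number in the report is produced by the public module operations; the
pipeline only orchestrates and serializes.  Groupings whose levels are too
small for a between-group test are degraded gracefully: singleton levels are
reported from their single study and dropped from the test, and groupings on
unpopulated moderators are skipped with a logged reason.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from . import bias as bias_mod
from . import moderators as mod_mod
from .effect_size import DEFAULT_FLAVOR, DEFAULT_VARIANCE, effect_table, effects_frame
from .pooling import classify_effect_size, forest_frame, pool_random_dl
from .sensitivity import leave_one_out, exclusion_analysis
from .study_data import StudyTable, builtin_table, min_total_n, read_study_table

logger = logging.getLogger("mpvmeta")

__all__ = ["PipelineOptions", "AnalysisReport", "run_pipeline"]

_DEFAULT_SUBGROUPS = ("diagnosis", "region_turkey", "instrument", "design",
                      "apd_recent", "nos_band")
_DEFAULT_METAREGS = ("age", "male_ratio")


@dataclass(frozen=True)
class PipelineOptions:
    flavor: str = DEFAULT_FLAVOR
    variance: str = DEFAULT_VARIANCE
    exact_j: bool = False
    metareg_tau2: str = "reml"
    kh: str = "untruncated"
    trimfill_estimator: str = "L0"
    trimfill_side: str = "auto"
    subgroups: tuple[str, ...] = _DEFAULT_SUBGROUPS
    metaregs: tuple[str, ...] = _DEFAULT_METAREGS
    exclude_small: Optional[int] = 100
    loo: bool = True
    seed: int = 0


@dataclass(frozen=True)
class AnalysisReport:
    input_digest: str
    settings: dict
    overall: dict
    subgroups: dict
    metaregressions: dict
    bias: dict
    sensitivity: dict

    def to_dict(self) -> dict:
        return {
            "input_digest": self.input_digest,
            "settings": self.settings,
            "overall": self.overall,
            "subgroups": self.subgroups,
            "metaregressions": self.metaregressions,
            "bias": self.bias,
            "sensitivity": self.sensitivity,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, default=_plain)


def _plain(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _asdict(obj) -> dict:
    return json.loads(json.dumps(dataclasses.asdict(obj), default=_plain))


def _digest(table: StudyTable) -> str:
    text = table.to_frame().to_csv(index=False, na_rep="NA")
    return hashlib.sha256(text.encode()).hexdigest()


def _load(table: Union[str, Path, StudyTable]) -> StudyTable:
    if isinstance(table, StudyTable):
        return table
    if str(table) == "builtin":
        return builtin_table()
    return read_study_table(table)


def run_pipeline(
    table: Union[str, Path, StudyTable] = "builtin",
    options: PipelineOptions = PipelineOptions(),
    out_dir: Optional[Union[str, Path]] = None,
) -> AnalysisReport:
    """Run the full analysis and (optionally) write report.json plus TSVs.

    ``table`` is a CSV path, the literal string ``"builtin"`` for the
    packaged 24-study table, or an in-memory :class:`StudyTable`.
    On any stage failure, partial output files are removed.
    """
    data = _load(table)
    opts = options
    ek = dict(flavor=opts.flavor, variance=opts.variance)
    logger.info("pipeline start: %d studies", len(data))

    effects = effect_table(data, exact_j=opts.exact_j, **ek)
    overall = pool_random_dl(effects)
    logger.info("overall pooling: theta=%.3f (%s), I2=%.1f%%",
                overall.theta_hat, classify_effect_size(overall.theta_hat), overall.I2)
    overall_block = _asdict(overall)
    overall_block["classification"] = classify_effect_size(overall.theta_hat)

    subgroups: dict = {}
    for name in opts.subgroups:
        subgroups[name] = _subgroup_block(data, name, opts)

    metaregs: dict = {}
    for name in opts.metaregs:
        try:
            res = mod_mod.meta_regress(
                data, name, tau2_method=opts.metareg_tau2, kh=opts.kh, **ek)
            metaregs[name] = _asdict(res)
            logger.info("meta-regression on %s: slope=%.4f p=%.4f k=%d",
                        name, res.slope(), res.p[name], res.k_used)
        except ValueError as exc:
            metaregs[name] = {"skipped": str(exc)}
            logger.info("meta-regression on %s skipped: %s", name, exc)

    bias_block: dict = {"overall": _bias_scope(effects, opts)}
    for level in ("depression", "anxiety", "bipolar", "schizophrenia"):
        sub = [e for e, r in zip(effects, data) if r.diagnosis == level]
        if len(sub) >= 3:
            bias_block[level] = _bias_scope(sub, opts)
        else:
            bias_block[level] = {"skipped": f"only {len(sub)} studies (need >= 3)"}

    sens: dict = {}
    if opts.loo:
        loo = leave_one_out(data, **ek)
        sens["leave_one_out"] = {
            "rows": {sid: _asdict(s) for sid, s in loo.rows.items()},
            "min_theta": loo.min_theta, "max_theta": loo.max_theta,
            "argmin": loo.argmin, "argmax": loo.argmax,
        }
        logger.info("leave-one-out: pooled SMD ranges %.3f..%.3f",
                    loo.min_theta, loo.max_theta)
    if opts.exclude_small is not None:
        try:
            s = exclusion_analysis(data, min_total_n(opts.exclude_small), **ek)
            sens[f"exclude_total_n_below_{opts.exclude_small}"] = _asdict(s)
        except ValueError as exc:
            sens[f"exclude_total_n_below_{opts.exclude_small}"] = {"skipped": str(exc)}

    report = AnalysisReport(
        input_digest=_digest(data),
        settings={**dataclasses.asdict(opts), "k": len(data)},
        overall=overall_block,
        subgroups=subgroups,
        metaregressions=metaregs,
        bias=bias_block,
        sensitivity=sens,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        try:
            p = out / "report.json"
            p.write_text(report.to_json())
            written.append(p)
            p = out / "effects.tsv"
            effects_frame(effects).to_csv(p, sep="\t", index=False)
            written.append(p)
            p = out / "forest.tsv"
            forest_frame(effects, overall).to_csv(p, sep="\t", index=False)
            written.append(p)
            p = out / "funnel.tsv"
            bias_mod.funnel_frame(effects).to_csv(p, sep="\t", index=False)
            written.append(p)
            if opts.loo:
                p = out / "leave_one_out.tsv"
                loo.to_frame().to_csv(p, sep="\t", index=False)
                written.append(p)
        except Exception:
            for p in written:
                p.unlink(missing_ok=True)
            raise
    return report


def _subgroup_block(data: StudyTable, name: str, opts: PipelineOptions) -> dict:
    """Subgroup analysis with graceful degradation for singleton levels."""
    ek = dict(flavor=opts.flavor, variance=opts.variance)
    group_fn = mod_mod.GROUPINGS.get(name)
    if group_fn is None:
        return {"skipped": f"unknown grouping {name!r}"}
    labelled = [(r, group_fn(r)) for r in data]
    present = [(r, g) for r, g in labelled if g is not None]
    if not present:
        logger.info("subgroup %s skipped: moderator unpopulated", name)
        return {"skipped": f"moderator behind grouping {name!r} is missing in every record"}

    counts: dict[str, int] = {}
    for _, g in present:
        counts[g] = counts.get(g, 0) + 1
    singletons = {g for g, c in counts.items() if c < 2}
    block: dict = {"level_counts": counts}
    for g in singletons:
        (rec,) = [r for r, gg in present if gg == g]
        est = effect_table(StudyTable((rec,)), **ek)[0]
        z = est.theta / est.se
        from scipy import stats as _st
        block.setdefault("singletons", {})[g] = {
            "study_id": rec.study_id,
            "theta": est.theta,
            "ci_low": est.theta - 1.959963984540054 * est.se,
            "ci_high": est.theta + 1.959963984540054 * est.se,
            "p": float(2 * _st.norm.sf(abs(z))),
        }
        logger.info("subgroup %s: singleton level %r reported from its one study", name, g)
    usable = [r for r, g in present if g not in singletons]
    levels_left = {g for _, g in present if g not in singletons}
    if len(levels_left) < 2:
        block["skipped"] = "fewer than 2 levels with k >= 2"
        return block
    try:
        res = mod_mod.subgroup_analysis(
            StudyTable(tuple(usable), provenance=data.provenance), name,
            tau2_method=opts.metareg_tau2, kh=opts.kh, **ek)
    except ValueError as exc:
        block["skipped"] = str(exc)
        return block
    block["per_group"] = {g: _asdict(s) for g, s in res.per_group.items()}
    block["between_F"] = res.between_F
    block["between_p"] = res.between_p
    block["df1"], block["df2"] = res.df1, res.df2
    block["Q_between"] = res.Q_between
    block["p_Q_between"] = res.p_Q_between
    logger.info("subgroup %s: %d levels, between F=%.2f p=%.3f",
                name, len(res.per_group), res.between_F, res.between_p)
    return block


def _bias_scope(effects, opts: PipelineOptions) -> dict:
    out: dict = {}
    try:
        out["egger"] = _asdict(bias_mod.egger_test(effects))
    except ValueError as exc:
        out["egger"] = {"skipped": str(exc)}
        return out
    try:
        tf = bias_mod.trim_and_fill(
            effects, side=opts.trimfill_side, estimator=opts.trimfill_estimator)
        out["trim_and_fill"] = {
            "side": tf.side, "estimator": tf.estimator, "k0": tf.k0,
            "iterations": tf.iterations, "adjusted": _asdict(tf.adjusted),
            "imputed": [_asdict(e) for e in tf.imputed_effects],
        }
    except (ValueError, RuntimeError) as exc:
        out["trim_and_fill"] = {"skipped": str(exc)}
    return out
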