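"""End-to-end pipeline: simulate or ingest raw tag logs per experimental
condition, preprocess them into contact networks, and compare two conditions
with the b2 model plus descriptive statistics.

Configuration lives in one YAML file; every preprocessing constant (the
120 s tag-reuse gap, the 150 cm contact threshold, the 10-contact / 80 cm /
25% / 60 s group criteria) is a named default that the file can override,
never an inline literal.  Each filtering stage logs how many records or
participants it dropped, so input counts always reconcile with retained plus
dropped.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import contacts as contacts_mod
from . import ingest, network, synthetic
from .b2 import B2Model, B2Spec
from .grouping import GroupParams, assign_groups, evaluate_all_pairs, groups_to_frame
from .stats import mann_whitney_u, simple_linreg, welch_t

logger = logging.getLogger(__name__)


@dataclass
class ConditionConfig:
    name: str
    raw_log: str | None = None
    window: tuple[int, int] | None = None
    ratings: str | None = None
    simulate: dict[str, Any] = field(default_factory=dict)


@dataclass
class PipelineConfig:
    output_dir: str = "out"
    seed: int = 0
    conditions: dict[str, ConditionConfig] = field(default_factory=dict)
    gap_threshold_s: int = ingest.DEFAULT_GAP_THRESHOLD_S
    contact_threshold_cm: int = contacts_mod.DEFAULT_CONTACT_THRESHOLD_CM
    min_contact_seconds: int = 1
    grouping: GroupParams = field(default_factory=GroupParams)
    b2: B2Spec = field(default_factory=B2Spec)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        conditions = {}
        for name, sub in (raw.pop("conditions", {}) or {}).items():
            sub = dict(sub or {})
            window = sub.pop("window", None)
            if window is not None:
                if len(window) != 2 or window[0] >= window[1]:
                    raise ValueError(f"conditions.{name}.window: need [t0, t1) with t0 < t1")
                window = (int(window[0]), int(window[1]))
            known = {"raw_log", "ratings", "simulate"}
            unknown = set(sub) - known
            if unknown:
                raise ValueError(f"conditions.{name}: unknown fields {sorted(unknown)}")
            conditions[name] = ConditionConfig(name=name, window=window, **sub)
        params = dict(raw.pop("parameters", {}) or {})
        try:
            grouping = GroupParams(**params.pop("grouping", {}))
        except TypeError as exc:
            raise ValueError(f"parameters.grouping: {exc}") from None
        try:
            b2 = B2Spec(**params.pop("b2", {}))
        except TypeError as exc:
            raise ValueError(f"parameters.b2: {exc}") from None
        cfg = cls(
            output_dir=str(raw.pop("output_dir", "out")),
            seed=int(raw.pop("seed", 0)),
            conditions=conditions,
            grouping=grouping,
            b2=b2,
            **{k: int(v) for k, v in params.items()
               if k in ("gap_threshold_s", "contact_threshold_cm", "min_contact_seconds")},
        )
        leftover = (set(params) - {"gap_threshold_s", "contact_threshold_cm",
                                   "min_contact_seconds"}) | set(raw)
        if leftover:
            raise ValueError(f"unknown config fields: {sorted(leftover)}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def condition_dir(self, name: str) -> Path:
        return Path(self.output_dir) / name

    def raw_log_path(self, name: str) -> Path:
        cond = self.conditions[name]
        if cond.raw_log:
            return Path(cond.raw_log)
        return self.condition_dir(name) / "raw_log.csv"

    def parameter_echo(self) -> dict[str, Any]:
        """All analysis parameters, for embedding in reports."""
        return {
            "seed": self.seed,
            "gap_threshold_s": self.gap_threshold_s,
            "contact_threshold_cm": self.contact_threshold_cm,
            "min_contact_seconds": self.min_contact_seconds,
            "grouping": dataclasses.asdict(self.grouping),
            "b2": dataclasses.asdict(self.b2),
        }


def _condition_seed(base_seed: int, name: str) -> int:
    digest = np.random.SeedSequence(
        [base_seed, *[ord(c) for c in name]]
    ).generate_state(1)[0]
    return int(digest % (2**31))


def cmd_simulate(config: PipelineConfig) -> dict[str, Path]:
    """Simulate a raw tag log per condition; writes ``raw_log.csv`` and
    ``ground_truth.json`` under the condition's output directory."""
    written = {}
    for name, cond in config.conditions.items():
        out_dir = config.condition_dir(name)
        out_dir.mkdir(parents=True, exist_ok=True)
        overrides = dict(cond.simulate)
        overrides.setdefault("seed", _condition_seed(config.seed, name))
        overrides.setdefault("condition_label", name)
        try:
            stream_cfg = synthetic.StreamConfig(**overrides)
        except TypeError as exc:
            raise ValueError(f"conditions.{name}.simulate: {exc}") from None
        records, truth = synthetic.simulate_tag_stream(stream_cfg)
        log_path = config.raw_log_path(name)
        synthetic.write_raw_log(records, log_path)
        truth.to_json(out_dir / "ground_truth.json")
        logger.info("simulate[%s]: %d records, %d participants",
                    name, len(records), len(truth.sessions))
        written[name] = log_path
    return written


@dataclass
class PreprocessResult:
    sessions: list[ingest.VisitSession]
    group_map: dict[str, str]
    qualifying: pd.DataFrame     # per-second qualifying contacts
    contacts: pd.DataFrame       # aggregated dyads
    net: network.ContactNetwork


def preprocess_condition(config: PipelineConfig, name: str) -> PreprocessResult:
    """Run the preprocessing chain for one condition and write all
    intermediate tables under the condition's output directory."""
    out_dir = config.condition_dir(name)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = ingest.parse_raw_log(config.raw_log_path(name))
    logger.info("preprocess[%s]: %d raw records", name, len(records))
    sessions = ingest.sessionize(records, config.gap_threshold_s)
    ingest.sessions_to_frame(sessions).to_csv(out_dir / "sessions.csv", index=False)
    annotated = ingest.assign_participants(records, sessions)
    pair_seconds = ingest.symmetrize(annotated)
    pair_seconds.to_csv(out_dir / "pair_seconds.csv", index=False)
    criteria = evaluate_all_pairs(pair_seconds, sessions, config.grouping)
    criteria.to_csv(out_dir / "pair_criteria.csv", index=False)
    participants = [s.participant_id for s in sessions]
    group_map = assign_groups(criteria, participants, config.grouping.min_criteria)
    groups_to_frame(group_map).to_csv(out_dir / "groups.csv", index=False)
    n_groups = len(set(group_map.values()))
    logger.info("preprocess[%s]: %d participants in %d groups",
                name, len(participants), n_groups)
    qualifying = contacts_mod.contact_seconds(
        pair_seconds, group_map, config.contact_threshold_cm
    )
    dyads = contacts_mod.aggregate_contacts(qualifying, config.min_contact_seconds)
    dyads.to_csv(out_dir / "contacts.csv", index=False)
    logger.info("preprocess[%s]: %d contact dyads (dropped %d same-group or "
                "distant pair-seconds)", name, len(dyads),
                len(pair_seconds) - len(qualifying))
    contacts_mod.participant_degree(dyads, participants).to_csv(
        out_dir / "participant_summary.csv", index=False
    )
    contacts_mod.hourly_summary(sessions, qualifying).to_csv(
        out_dir / "hourly_summary.csv", index=False
    )
    net = network.build_network(participants, dyads)
    network.write_edge_list(net, out_dir / "edges.csv", out_dir / "nodes.csv")
    return PreprocessResult(sessions, group_map, qualifying, dyads, net)


def cmd_preprocess(config: PipelineConfig) -> dict[str, PreprocessResult]:
    return {name: preprocess_condition(config, name) for name in config.conditions}


def _windowed(config: PipelineConfig, name: str, pre: PreprocessResult):
    cond = config.conditions[name]
    if cond.window is None:
        participants = [s.participant_id for s in pre.sessions]
        return participants, pre.contacts
    t0, t1 = cond.window
    return contacts_mod.select_window(
        pre.sessions, pre.qualifying, t0, t1, config.min_contact_seconds
    )


def _prefix(frame: pd.DataFrame, contacts: pd.DataFrame, name: str):
    """Prefix participant ids with the condition so stacked actor sets are
    disjoint even when tag ids repeat across days."""
    ren = lambda p: f"{name}:{p}"  # noqa: E731
    out = contacts.copy()
    out["participant_a"] = out["participant_a"].map(ren)
    out["participant_b"] = out["participant_b"].map(ren)
    return [ren(p) for p in frame], out


def cmd_compare(
    config: PipelineConfig,
    condition_a: str,
    condition_b: str,
    preprocessed: dict[str, PreprocessResult] | None = None,
) -> dict[str, Any]:
    """Compare two preprocessed conditions.

    Produces Table-style descriptives per condition (range, mean ± SD,
    median, IQR of degrees and contact durations), the b2 odds ratio for the
    condition dummy with its 95% credible interval, a Mann-Whitney U test on
    per-dyad contact durations, Welch t tests on any shared rating columns,
    a crowdedness regression over the pooled hourly summaries, and an echo
    of every parameter used.  Written to ``<output_dir>/report_<a>_vs_<b>.json``.
    """
    for name in (condition_a, condition_b):
        if name not in config.conditions:
            raise ValueError(f"unknown condition {name!r}")
    if preprocessed is None:
        preprocessed = {name: preprocess_condition(config, name)
                        for name in (condition_a, condition_b)}
    report: dict[str, Any] = {
        "conditions": [condition_a, condition_b],
        "parameters": config.parameter_echo(),
    }

    nets = {}
    durations = {}
    descriptives = {}
    hourly_frames = []
    for name in (condition_a, condition_b):
        pre = preprocessed[name]
        participants, dyads = _windowed(config, name, pre)
        p_pref, dyads_pref = _prefix(participants, dyads, name)
        nets[name] = network.build_network(p_pref, dyads_pref)
        durations[name] = dyads["contact_seconds"].to_numpy(dtype=float)
        descriptives[name] = contacts_mod.condition_descriptives(dyads_pref, p_pref)
        hourly_frames.append(contacts_mod.hourly_summary(pre.sessions, pre.qualifying))
    report["descriptives"] = descriptives

    combined = network.combine_networks(nets[condition_a], nets[condition_b], "condition")
    spec = dataclasses.replace(config.b2, seed=_condition_seed(config.seed, "b2"))
    results = B2Model(combined, spec).fit()
    or_summary = results.summarize_or("condition")
    diag = results.diagnostics()
    report["b2"] = {
        "covariate": "condition",
        "or_point": or_summary.or_point,
        "ci_low": or_summary.ci_low,
        "ci_high": or_summary.ci_high,
        "formatted": str(or_summary),
        "posterior_mean_mu": results.posterior_mean("mu"),
        "posterior_mean_sigma_a": results.posterior_mean("sigma_a"),
        "acceptance": results.acceptance,
        "diagnostics": diag.to_dict(orient="records"),
    }
    results.to_frame().to_csv(
        Path(config.output_dir) / f"b2_draws_{condition_a}_vs_{condition_b}.csv",
        index=False,
    )

    if len(durations[condition_a]) and len(durations[condition_b]):
        mw = mann_whitney_u(durations[condition_a], durations[condition_b])
        report["duration_test"] = {
            "U": mw.statistic, "p_value": mw.p_value, "method": mw.method,
            "n1": mw.n1, "n2": mw.n2,
        }

    ratings = {}
    for name in (condition_a, condition_b):
        path = config.conditions[name].ratings
        if path:
            ratings[name] = pd.read_csv(path)
    if len(ratings) == 2:
        shared = [c for c in ratings[condition_a].columns
                  if c in ratings[condition_b].columns]
        report["rating_tests"] = {}
        for col in shared:
            res = welch_t(ratings[condition_a][col].dropna(),
                          ratings[condition_b][col].dropna())
            report["rating_tests"][col] = {
                "t": res.statistic, "df": res.df, "p_value": res.p_value,
                "n1": res.n1, "n2": res.n2,
            }

    hourly = pd.concat(hourly_frames, ignore_index=True).dropna()
    if len(hourly) >= 3 and hourly["n_participants"].nunique() > 1:
        reg = simple_linreg(hourly["n_participants"], hourly["median_degree"])
        report["crowdedness_regression"] = {
            "slope": reg.slope, "intercept": reg.intercept, "F": reg.f_stat,
            "df1": reg.df1, "df2": reg.df2, "p_value": reg.p_value,
            "r_squared": reg.r_squared, "n_hours": reg.n,
        }

    out_path = Path(config.output_dir) / f"report_{condition_a}_vs_{condition_b}.json"
    out_path.parent.mkdir(parents=True, exist_ok=True)
    out_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    logger.info("compare[%s vs %s]: %s", condition_a, condition_b, or_summary)
    return report
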