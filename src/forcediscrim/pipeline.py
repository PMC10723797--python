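"""End-to-end orchestration: simulate/ingest -> preprocess -> fit -> compare.

A run is fully specified by a :class:`RunConfig` (serialisable to/from YAML)
and is reproducible bit-for-bit from (config, seed): all randomness flows
through the seed, and every emitted JSON file is written with sorted keys and
no timestamps.  The result of a run is a :class:`ResultsBundle` holding the
exclusion ledger, the tidy per-fit table, the planned PSE and JND contrasts,
kinematic summaries, and a provenance block (config hash, seed, version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .inference import (
    CONTRAST_PLANS,
    AnovaResult,
    ContrastResult,
    PairedComparisonResult,
    compare_conditions,
    oneway_anova,
)
from .observer import (
    ExperimentDesign,
    ConditionSpec,
    KinematicParams,
    PopulationSpec,
    default_population,
    inject_anomalies,
    make_design,
    read_trials,
    simulate_cohort,
)
from .preprocess import (
    ExclusionReport,
    apply_exclusions,
    kinematic_summaries,
    rules_for_design,
)
from .psychometric import fit_table

__all__ = [
    "RunConfig",
    "ResultsBundle",
    "run_experiment",
    "cross_experiment_anova",
    "render_report",
    "load_bundle",
    "load_pse_table",
]

logger = logging.getLogger("forcediscrim")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    experiment: str = "exp1"
    mode: str = "simulate"  # "simulate" | "ingest"
    n_participants: int = 30
    seed: int = 0
    trials_path: str | None = None  # ingest mode
    population: PopulationSpec | None = None  # None -> preset default
    anomaly_rates: Mapping[str, float] = field(default_factory=dict)
    alpha: float = 0.05
    bf_scale: float = 0.707
    force_jitter_sd: float = 0.01
    output_dir: str | None = None
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.population is not None:
            d["population"] = _population_to_dict(self.population)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        pop = d.get("population")
        if isinstance(pop, Mapping):
            d["population"] = _population_from_dict(pop)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _population_to_dict(pop: PopulationSpec) -> dict:
    return {
        "per_condition": {
            c: dataclasses.asdict(s) for c, s in pop.per_condition.items()
        },
        "lapse_rate": pop.lapse_rate,
        "response_missing_rate": pop.response_missing_rate,
        "kinematics": dataclasses.asdict(pop.kinematics),
    }


def _population_from_dict(d: Mapping) -> PopulationSpec:
    kin = d.get("kinematics")
    return PopulationSpec(
        per_condition={
            c: ConditionSpec(**s) for c, s in d["per_condition"].items()
        },
        lapse_rate=float(d.get("lapse_rate", 0.0)),
        response_missing_rate=float(d.get("response_missing_rate", 0.0)),
        kinematics=KinematicParams(**kin) if kin else KinematicParams(),
    )


# ---------------------------------------------------------------------------
# Results bundle
# ---------------------------------------------------------------------------

@dataclass
class ResultsBundle:
    experiment: str
    design: ExperimentDesign
    exclusion_report: ExclusionReport
    fits: pd.DataFrame
    contrasts: dict[str, list[ContrastResult]]
    kinematics: pd.DataFrame | None
    dropped_participants: list[str]
    provenance: dict

    def contrasts_dict(self) -> dict:
        return {
            measure: [c.to_dict() for c in lst]
            for measure, lst in self.contrasts.items()
        }

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.exclusion_report.to_json(out / "exclusion_report.json")
        self.fits.to_csv(out / "fits.csv", index=False)
        with open(out / "contrasts.json", "w") as fh:
            json.dump(self.contrasts_dict(), fh, indent=2, sort_keys=True)
        if self.kinematics is not None:
            self.kinematics.to_csv(out / "kinematics.csv")
        with open(out / "provenance.json", "w") as fh:
            json.dump(
                {
                    **self.provenance,
                    "experiment": self.experiment,
                    "dropped_participants": self.dropped_participants,
                },
                fh, indent=2, sort_keys=True,
            )


# ---------------------------------------------------------------------------
# Run
# ---------------------------------------------------------------------------

def run_experiment(
    config: RunConfig, trials: pd.DataFrame | None = None
) -> ResultsBundle:
    """Execute the full pipeline for one experiment.

    In simulate mode the cohort is generated from the preset design and the
    configured (or default) population, with anomalies injected at the
    configured rates.  In ingest mode ``trials`` (or ``config.trials_path``)
    supplies the trial table.  Participants with a degenerate fit in any
    condition are dropped listwise from the contrasts and recorded.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    design = make_design(config.experiment)
    if config.mode == "simulate":
        population = config.population or default_population(config.experiment)
        logger.info(
            "simulating %d participants of %s with seed %d",
            config.n_participants, config.experiment, config.seed,
        )
        trials = simulate_cohort(
            config.n_participants, design, population, config.seed,
            force_jitter_sd=config.force_jitter_sd,
        )
        if config.anomaly_rates:
            trials, injected = inject_anomalies(
                trials, config.anomaly_rates, seed=config.seed + 1
            )
            logger.info("injected anomalies: %s", injected)
    elif config.mode == "ingest":
        if trials is None:
            if config.trials_path is None:
                raise ValueError("ingest mode needs trials or trials_path")
            trials = read_trials(config.trials_path)
    else:
        raise ValueError(f"unknown mode: {config.mode!r}")

    rules = rules_for_design(design)
    clean, report = apply_exclusions(trials, rules, design.comparison_levels)
    logger.info(
        "excluded %d/%d trials (%.1f%%): %s",
        report.excluded_total, report.total_trials,
        report.excluded_percent(1), report.excluded_by_reason,
    )

    fits = fit_table(clean)
    bad = fits.loc[
        ~fits["converged"] | fits["separation_flag"] | fits["pse"].isna(),
        "participant_id",
    ]
    dropped = sorted(set(bad.astype(str)))
    if dropped:
        logger.info("dropping participants with degenerate fits: %s", dropped)
    usable = fits[~fits["participant_id"].astype(str).isin(dropped)]
    if usable.empty:
        raise ValueError("all participants excluded or degenerate; nothing to compare")

    plan = CONTRAST_PLANS[config.experiment]
    contrasts = {
        measure: compare_conditions(
            usable, plan, measure=measure,
            alpha=config.alpha, bf_scale=config.bf_scale,
        )
        for measure in ("pse", "jnd")
    }

    kinematics = None
    if {"endpoint_offset_mm", "force_lead_time_ms"}.issubset(clean.columns):
        kinematics = kinematic_summaries(clean)

    bundle = ResultsBundle(
        experiment=config.experiment,
        design=design,
        exclusion_report=report,
        fits=fits,
        contrasts=contrasts,
        kinematics=kinematics,
        dropped_participants=dropped,
        provenance={
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": __version__,
        },
    )
    if config.output_dir:
        bundle.write(config.output_dir)
    return bundle


# ---------------------------------------------------------------------------
# Cross-experiment ANOVA
# ---------------------------------------------------------------------------

#: Supported per-participant difference vectors for the between-experiment ANOVA.
CROSS_DIFFERENCES = (
    "contact_minus_no_contact",
    "baseline_minus_no_contact",
    "force_lead_time_diff",
)


def _difference_vector(bundle: ResultsBundle, difference: str) -> np.ndarray:
    if difference == "force_lead_time_diff":
        if bundle.kinematics is None:
            raise ValueError("bundle has no kinematic summaries")
        col = "force_lead_time_ms:contact_minus_no_contact"
        return bundle.kinematics[col].dropna().to_numpy()
    wide = bundle.fits.pivot_table(
        index="participant_id", columns="condition", values="pse", aggfunc="first"
    )
    if difference == "contact_minus_no_contact":
        d = wide["contact"] - wide["no_contact"]
    elif difference == "baseline_minus_no_contact":
        d = wide["baseline"] - wide["no_contact"]
    else:
        raise ValueError(f"unknown difference: {difference!r}")
    return d.dropna().to_numpy()


def cross_experiment_anova(
    bundles: Sequence[ResultsBundle], difference: str = "contact_minus_no_contact"
) -> AnovaResult:
    """One-way between-subjects ANOVA of a per-participant difference across
    experiments, with Bonferroni-corrected pooled-t post hocs."""
    if len(bundles) < 2:
        raise ValueError("cross-experiment ANOVA needs >= 2 bundles")
    groups = [_difference_vector(b, difference) for b in bundles]
    labels = [b.experiment for b in bundles]
    return oneway_anova(groups, labels=labels)


# ---------------------------------------------------------------------------
# Ingesting deposited per-participant tables
# ---------------------------------------------------------------------------

def load_pse_table(path) -> pd.DataFrame:
    """Load a per-participant PSE/JND table (long CSV) for the contrast battery.

    Accepts columns ``participant_id`` (or ``participant``), ``condition``,
    ``pse`` and optionally ``jnd``; returns the normalised long table that
    :func:`forcediscrim.inference.compare_conditions` consumes directly.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    rename = {}
    for want, alts in {
        "participant_id": ("participant_id", "participant", "subject", "id"),
        "condition": ("condition",),
        "pse": ("pse",),
        "jnd": ("jnd",),
    }.items():
        for alt in alts:
            if alt in cols:
                rename[cols[alt]] = want
                break
    df = df.rename(columns=rename)
    needed = {"participant_id", "condition", "pse"}
    if not needed.issubset(df.columns):
        raise ValueError(
            f"PSE table needs columns {sorted(needed)}; got {list(df.columns)}"
        )
    return df


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

def _format_result(c: dict) -> str:
    """Render one contrast in the conventional reporting style."""
    ci = c["ci95"]
    if c["test"] == "paired_t":
        s = (
            f"t({c['df']}) = {c['statistic']:.2f}, p = {c['p']:.3f}, "
            f"d = {c['effect_size']:.2f}, "
            f"CI95 = [{ci[0]:.2f}, {ci[1]:.2f}]"
        )
    else:
        s = (
            f"W = {c['statistic']:.2f}, p = {c['p']:.3f}, "
            f"r_rb = {c['effect_size']:.2f}, "
            f"CI95 = [{ci[0]:.2f}, {ci[1]:.2f}]"
        )
    if c.get("bf01") is not None:
        s += f", BF01 = {c['bf01']:.2f}"
    return s


def render_report(bundle: ResultsBundle, outdir) -> list[Path]:
    """Write figures and a plain-text summary for one results bundle.

    Emits group psychometric curves per condition (mean of per-participant
    fitted curves), a PSE box/strip plot, and ``summary.txt`` with every
    planned contrast in ``t(df) = ..., p = ..., d = ..., CI95 = [...]``
    format plus an appendix of degenerate fits.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    fits = bundle.fits
    ok = fits[fits["converged"] & ~fits["separation_flag"] & fits["pse"].notna()]
    xs = np.linspace(0.8, 3.2, 200)
    fig, ax = plt.subplots(figsize=(5, 4))
    for cond, grp in ok.groupby("condition"):
        curves = [
            1.0 / (1.0 + np.exp(-(b0 + b1 * xs)))
            for b0, b1 in zip(grp["beta0"], grp["beta1"])
        ]
        ax.plot(xs, np.mean(curves, axis=0), label=cond)
    ax.axhline(0.5, color="grey", lw=0.5, ls="--")
    ax.set_xlabel("comparison force (N)")
    ax.set_ylabel("P(comparison stronger)")
    ax.set_title(f"{bundle.experiment}: group psychometric curves")
    ax.legend()
    fig.tight_layout()
    p = out / "psychometric_curves.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    fig, ax = plt.subplots(figsize=(5, 4))
    conds = sorted(ok["condition"].unique())
    data = [ok.loc[ok["condition"] == c, "pse"].to_numpy() for c in conds]
    if data:
        ax.boxplot(data, tick_labels=conds)
        rng = np.random.default_rng(0)  # jitter for the strip overlay only
        for i, vals in enumerate(data, start=1):
            ax.plot(
                i + rng.uniform(-0.08, 0.08, len(vals)), vals,
                "o", ms=3, alpha=0.5,
            )
    ax.set_ylabel("PSE (N)")
    ax.set_title(f"{bundle.experiment}: PSE by condition")
    fig.tight_layout()
    p = out / "pse_by_condition.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    lines = [f"Run report — {bundle.experiment}", "=" * 40, ""]
    rep = bundle.exclusion_report
    lines.append(
        f"Trials: {rep.total_trials}; excluded {rep.excluded_total} "
        f"({rep.excluded_percent(1)}%): {rep.excluded_by_reason or 'none'}"
    )
    lines.append("")
    for measure, contrasts in bundle.contrasts_dict().items():
        lines.append(f"{measure.upper()} contrasts:")
        if not contrasts:
            lines.append("  no contrasts")
        for c in contrasts:
            lines.append(f"  {c['contrast']}: {_format_result(c)}")
        lines.append("")
    if bundle.dropped_participants:
        lines.append("Appendix — participants dropped (degenerate fits):")
        for pid in bundle.dropped_participants:
            lines.append(f"  {pid}")
    else:
        lines.append("No degenerate fits.")
    p = out / "summary.txt"
    p.write_text("\n".join(lines) + "\n")
    written.append(p)
    return written


def load_bundle(bundle_dir) -> ResultsBundle:
    """Reconstruct a (renderable) bundle from the files written by ``write``."""
    bdir = Path(bundle_dir)
    with open(bdir / "provenance.json") as fh:
        prov = json.load(fh)
    with open(bdir / "exclusion_report.json") as fh:
        rep = json.load(fh)
    with open(bdir / "contrasts.json") as fh:
        raw_contrasts = json.load(fh)
    fits = pd.read_csv(bdir / "fits.csv")
    experiment = prov.pop("experiment")
    dropped = prov.pop("dropped_participants", [])
    contrasts = {
        measure: [_contrast_from_dict(c, measure) for c in lst]
        for measure, lst in raw_contrasts.items()
    }
    kin_path = bdir / "kinematics.csv"
    kinematics = pd.read_csv(kin_path, index_col=0) if kin_path.exists() else None
    report = ExclusionReport(
        total_trials=rep["total_trials"],
        excluded_by_reason=rep["excluded_by_reason"],
        per_participant=rep.get("per_participant", {}),
    )
    return ResultsBundle(
        experiment=experiment,
        design=make_design(experiment),
        exclusion_report=report,
        fits=fits,
        contrasts=contrasts,
        kinematics=kinematics,
        dropped_participants=dropped,
        provenance=prov,
    )


def _contrast_from_dict(c: Mapping, measure: str) -> ContrastResult:
    a, b = c["contrast"].split("-", 1)
    res = PairedComparisonResult(
        test_used=c["test"],
        statistic=c["statistic"],
        df=c["df"],
        p_value=c["p"],
        effect_size=c["effect_size"],
        effect_size_name=c["effect_size_name"],
        ci95=tuple(c["ci95"]),
        estimate=c["estimate"],
        n_pairs=c["n_pairs"],
        bf01=c.get("bf01"),
        bf01_label=c.get("bf01_label"),
    )
    return ContrastResult(
        condition_a=a, condition_b=b, measure=measure, result=res,
        n_dropped=c.get("n_dropped", 0),
    )
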