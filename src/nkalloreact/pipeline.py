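"""Pipeline stages tying the library into a reproducible workflow.

Each stage reads/writes plain files under an output directory and
records the resolved configuration and seed for provenance:
``simulate`` -> genotype/pairs/outcomes tables, ``score`` -> the pairs x
27-models matrix, ``correlate`` -> Spearman matrices and heatmaps per
cohort, ``outcomes`` -> cumulative-incidence curves and Gray-test
reports per model x event.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

from . import __version__
from .genotypes import OutcomeRecord, read_cohort, verify_match_fashion, write_cohort
from .models import MODEL_IDS, load_default_tables, score_cohort
from .simulate import OutcomeSimConfig, simulate_cohort, simulate_outcomes
from .stats import encode_scores, gray_test_records, records_to_arrays, aalen_johansen, spearman_matrix

log = logging.getLogger("nkalloreact")

__all__ = ["RunConfig", "run_simulate", "run_score", "run_correlate", "run_outcomes"]

#: models grouped for outcome analysis by default (ordinal levels as groups)
DEFAULT_OUTCOME_MODELS = (
    "Cen-B", "Tel-B", "B-pattern", "KIR-B content",
    "L/L synthesis", "R/L qualitative", "Educ-DL synthesis", "Educ-2DS1",
)


@dataclass
class RunConfig:
    out_dir: str = "results"
    seed: int = 0
    n_genoidentical: int = 43
    n_haploidentical: int = 35
    include_nonclassical_bw: bool = True
    alpha: float = 0.05
    outcome_models: tuple[str, ...] = DEFAULT_OUTCOME_MODELS
    events: tuple[str, ...] = ("death", "relapse", "agvhd", "cgvhd")
    driver_model: str | None = None
    driver_event: str = "agvhd"
    log_hr_per_unit: float = 0.0
    censoring_months: float = 36.0

    def resolve_out(self) -> Path:
        out = Path(self.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "run_config.json", "w") as fh:
            json.dump({"version": __version__, **asdict(self)}, fh, indent=2, default=str)
        return out


def run_simulate(cfg: RunConfig) -> dict[str, Path]:
    """Simulate a cohort and write the three input tables."""
    out = cfg.resolve_out()
    pairs = simulate_cohort(cfg.n_genoidentical, cfg.n_haploidentical, cfg.seed)
    bad = [p.pair_id for p in pairs if not verify_match_fashion(p).consistent]
    if bad:  # structural guarantee of the generator
        raise AssertionError(f"simulated pairs fail match verification: {bad}")
    scores = None
    driver_scores = None
    if cfg.driver_model:
        scores = score_cohort(pairs)
        driver_scores = scores.codes_frame()[cfg.driver_model].to_dict()
    sim_cfg = OutcomeSimConfig(
        driver_model=cfg.driver_model,
        driver_event=cfg.driver_event,
        log_hr_per_unit=cfg.log_hr_per_unit,
        censoring_months=cfg.censoring_months,
    )
    records = simulate_outcomes(
        [p.pair_id for p in pairs], sim_cfg,
        np.random.default_rng((cfg.seed, 1)), driver_scores,
    )
    paths = {
        "pairs": out / "pairs.csv",
        "genotypes": out / "genotypes.csv",
        "outcomes": out / "outcomes.csv",
    }
    write_cohort(pairs, paths["pairs"], paths["genotypes"], records, paths["outcomes"])
    log.info("simulated %d pairs -> %s", len(pairs), out)
    return paths


def run_score(cfg: RunConfig, pairs_path, genotypes_path) -> dict[str, Path]:
    """Score all 27 models for every pair and write label + code matrices."""
    out = cfg.resolve_out()
    pairs, _ = read_cohort(pairs_path, genotypes_path)
    tables = load_default_tables()
    matrix = score_cohort(pairs, tables)
    paths = {
        "labels": out / "scores_labels.csv",
        "codes": out / "scores_codes.csv",
        "fashion": out / "pair_fashion.csv",
    }
    matrix.to_csv(paths["labels"], paths["codes"])
    pd.Series(matrix.match_fashion, name="match_fashion").rename_axis(
        "pair_id"
    ).to_csv(paths["fashion"])
    n_missing = int(matrix.codes_frame().isna().sum().sum())
    log.info("scored %d pairs x %d models (%d missing cells)",
             len(pairs), len(MODEL_IDS), n_missing)
    return paths


def _heatmap(rho: pd.DataFrame, path: Path, title: str) -> None:
    fig, ax = plt.subplots(figsize=(11, 9))
    sns.heatmap(
        rho, vmin=-1, vmax=1, cmap="RdBu_r", center=0, square=True,
        linewidths=0.3, cbar_kws={"label": "Spearman rho"}, ax=ax,
    )
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_correlate(cfg: RunConfig, codes_path, fashion_path) -> dict[str, Path]:
    """Spearman correlation matrix + heatmap per cohort and pooled."""
    out = cfg.resolve_out()
    codes = pd.read_csv(codes_path, index_col="pair_id")
    fashion = pd.read_csv(fashion_path, index_col="pair_id")["match_fashion"]
    paths: dict[str, Path] = {}
    subsets = {
        "genoidentical": codes.loc[fashion == "genoidentical"],
        "haploidentical": codes.loc[fashion == "haploidentical"],
        "pooled": codes,
    }
    for name, sub in subsets.items():
        if sub.empty:
            log.warning("cohort %s absent; skipping correlation output", name)
            continue
        cm = spearman_matrix(sub)
        csv_path = out / f"spearman_{name}.csv"
        cm.to_csv(csv_path, out / f"spearman_{name}_n.csv")
        _heatmap(cm.rho, out / f"spearman_{name}.png",
                 f"Model correlations ({name}, n={len(sub)})")
        paths[name] = csv_path
    return paths


def _cif_plot(groups: dict[str, tuple[np.ndarray, np.ndarray]],
              path: Path, title: str, horizon: float) -> None:
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for label, (t, cif) in sorted(groups.items()):
        ax.step(np.concatenate([[0], t]), np.concatenate([[0], cif]),
                where="post", label=str(label))
    ax.set_xlim(0, horizon)
    ax.set_ylim(0, 1)
    ax.set_xlabel("months from transplant")
    ax.set_ylabel("cumulative incidence")
    ax.set_title(title)
    ax.legend(title="model level", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_outcomes(cfg: RunConfig, codes_path, outcomes_path, labels_path=None) -> Path:
    """Gray-test report and cumulative-incidence plot per model x event.

    Pairs are grouped by the model's observed ordinal levels; death uses
    all-cause survival (no competing event), other events treat death as
    the competing risk.
    """
    out = cfg.resolve_out()
    codes = pd.read_csv(codes_path, index_col="pair_id")
    out_df = pd.read_csv(outcomes_path)
    records = [
        OutcomeRecord(str(r.pair_id), r.event, float(r.time_months), r.status)
        for r in out_df.itertuples()
    ]
    report_rows = []
    for event in cfg.events:
        ev_records = [r for r in records if r.event == event]
        if not ev_records:
            log.warning("no records for event %s; skipped", event)
            continue
        for model in cfg.outcome_models:
            col = codes[model]
            groups = {pid: (None if pd.isna(v) else v) for pid, v in col.items()}
            levels = sorted({v for v in groups.values() if v is not None})
            if len(levels) < 2:
                continue
            res = gray_test_records(ev_records, groups)
            report_rows.append(
                {
                    "event": event, "model": model,
                    "statistic": res.statistic, "df": res.df,
                    "p_value": res.p_value, "degenerate": res.degenerate,
                    "n_groups": len(levels),
                    "significant": bool(res.p_value < cfg.alpha),
                }
            )
            curves = {}
            for lev in levels:
                sel = [r for r in ev_records if groups.get(r.pair_id) == lev]
                if not sel:
                    continue
                t, s, _ = records_to_arrays(sel)
                c = aalen_johansen(t, s, event=event, group=str(lev))
                curves[f"{lev:g}"] = (c.times, c.cif)
            _cif_plot(
                curves,
                out / f"cif_{event}_{model.replace('/', '_').replace(' ', '_')}.png",
                f"{event} by {model}", cfg.censoring_months,
            )
    report = pd.DataFrame(report_rows)
    report_path = out / "gray_tests.csv"
    report.to_csv(report_path, index=False)
    with open(out / "gray_tests.json", "w") as fh:
        json.dump(report_rows, fh, indent=2)
    return report_path
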