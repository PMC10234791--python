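"""The end-to-end analysis as a model / results pair.

:class:`PaternalInvolvementModel` holds one analysis-ready table — one
row per participant with the facial metrics (objective dimorphism,
attractiveness, perceived masculinity, perceived paternal involvement)
and self-report scores (NFS, FIS-involved, FIS-desired) — together with
an :class:`AnalysisConfig`.  ``fit()`` runs the full inferential
procedure and returns a :class:`PaternalInvolvementResults`:

* correlations among the four outcomes, for the full sample and the
  fathers-only subset;
* for each sample x focal-predictor combination, a standardized
  regression of every outcome on the focal predictor (plus facial
  attractiveness as covariate unless disabled), each variable
  winsorised to +/- ``winsor_k`` SD within the analysis sample;
* a JZS default Bayes factor for each focal effect (full vs reduced
  model);
* a structured run log with per-model ns and winsorisation counts.

``from_study`` builds the table from raw study materials (landmark
files, rating records, self-report items), running the morphometric
scoring, rater filtering and aggregation, scale scoring, and the
participant exclusion funnel.  ``replicate_from_csv`` runs the same
analysis on an externally supplied table (replication mode).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import ratings as ratings_mod
from . import scales as scales_mod
from .morphometry import dimorphism_pipeline
from .stats import (
    JZS_DEFAULT_SCALE,
    EffectResult,
    jzs_bf,
    pearson,
    standardized_ols,
    winsorize,
)

__all__ = [
    "AnalysisConfig",
    "PaternalInvolvementModel",
    "PaternalInvolvementResults",
    "replicate_from_csv",
]

OUTCOME_COLUMNS = (
    "nfs",
    "fis_involved",
    "fis_desired",
    "perceived_paternal_involvement",
)
PREDICTOR_COLUMNS = ("objective_dimorphism", "perceived_masculinity")
REQUIRED_COLUMNS = (
    ("participant_id", "is_father", "attractiveness")
    + PREDICTOR_COLUMNS
    + OUTCOME_COLUMNS
)

_STARS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings of the inferential pipeline."""

    samples: tuple = ("full", "fathers_only")
    predictors: tuple = PREDICTOR_COLUMNS
    outcomes: tuple = OUTCOME_COLUMNS
    include_attractiveness: bool = True
    winsor_k: float = 3.0
    alpha: float = 0.05
    bf_prior_scale: float = JZS_DEFAULT_SCALE
    compute_bayes_factors: bool = True

    def __post_init__(self) -> None:
        if not self.outcomes:
            raise ValueError("at least one outcome required")
        bad = set(self.samples) - {"full", "fathers_only"}
        if bad:
            raise ValueError(f"unknown samples: {bad}")
        bad = set(self.predictors) - set(PREDICTOR_COLUMNS)
        if bad:
            raise ValueError(f"unknown predictors: {bad}")


class PaternalInvolvementModel:
    """Regression analysis of facial metrics against involvement scores."""

    def __init__(self, data: pd.DataFrame, config: AnalysisConfig | None = None):
        missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"analysis table missing columns: {missing}")
        if data.empty:
            raise ValueError("empty analysis table")
        self.data = data.reset_index(drop=True)
        self.config = config or AnalysisConfig()

    # ------------------------------------------------------- constructors

    @classmethod
    def from_study(
        cls,
        ref_female,
        ref_male,
        participants,
        rating_records: pd.DataFrame,
        selfreports: pd.DataFrame,
        config: AnalysisConfig | None = None,
        rater_subgroup: str = "all",
        seriousness_threshold: int = 5,
    ) -> "PaternalInvolvementModel":
        """Build the analysis table from raw study materials.

        Runs, in order: the participant exclusion funnel on the
        self-report roster; scale scoring; joint-GPA dimorphism scoring
        of the participant faces against the sex references; rater
        filtering and per-face rating aggregation (optionally for one
        rater-sex subgroup).  Participants surviving the funnel are
        matched to faces and ratings by id.
        """
        kept, funnel = scales_mod.apply_participant_exclusions(
            selfreports, seriousness_threshold
        )
        scores = scales_mod.score_participants(kept)

        kept_ids = set(scores["participant_id"])
        faces = [p for p in participants if p.face_id in kept_ids]
        if not faces:
            raise ValueError("no participant faces match the kept roster")
        dscores = dimorphism_pipeline(faces, ref_female, ref_male)
        dim = pd.DataFrame(
            {"participant_id": dscores.ids, "objective_dimorphism": dscores.raw}
        )

        filtered, rater_report = ratings_mod.filter_raters(
            rating_records, seriousness_threshold
        )
        wide = ratings_mod.aggregate_all(filtered, subgroup=rater_subgroup)
        wide = wide.rename(columns={"face_id": "participant_id"})
        rating_cols = ["participant_id"] + list(ratings_mod.TRAITS)

        table = (
            scores.merge(dim, on="participant_id", how="inner")
            .merge(wide[rating_cols], on="participant_id", how="left")
        )
        model = cls(table, config)
        model.exclusion_report = funnel
        model.rater_report = rater_report
        return model

    # --------------------------------------------------------------- fit

    def fit(self) -> "PaternalInvolvementResults":
        cfg = self.config
        effects: list[dict] = []
        correlations: dict[str, pd.DataFrame] = {}
        log: list[dict] = []

        for sample in cfg.samples:
            sub = self._subset(sample)
            wins, clip_counts = self._winsorise_sample(sub)
            correlations[sample] = self._outcome_correlations(wins)
            log.append(
                {
                    "event": "sample",
                    "sample": sample,
                    "n": int(len(sub)),
                    "winsorised_values": clip_counts,
                }
            )
            for predictor in cfg.predictors:
                for outcome in cfg.outcomes:
                    res = self._fit_one(wins, sample, predictor, outcome)
                    effects.extend(r.as_dict() | {
                        "sample": sample, "model_predictor": predictor,
                    } for r in res)
                    log.append(
                        {
                            "event": "model",
                            "sample": sample,
                            "predictor": predictor,
                            "outcome": outcome,
                            "n": res[0].n,
                        }
                    )

        eff = pd.DataFrame(effects)[
            ["sample", "model_predictor", "outcome", "predictor",
             "beta", "t", "df", "p", "bf10", "n"]
        ]
        return PaternalInvolvementResults(
            effects=eff, correlations=correlations, config=cfg, run_log=log
        )

    # ----------------------------------------------------------- helpers

    def _subset(self, sample: str) -> pd.DataFrame:
        if sample == "full":
            sub = self.data
        else:
            sub = self.data[self.data["is_father"].astype(bool)]
        if sub.empty:
            raise ValueError(f"sample {sample!r} is empty")
        return sub.reset_index(drop=True)

    def _winsorise_sample(self, sub: pd.DataFrame):
        """Winsorise every continuous column within the analysis sample."""
        cols = [
            c
            for c in set(OUTCOME_COLUMNS)
            | set(PREDICTOR_COLUMNS)
            | {"attractiveness"}
            if c in sub.columns
        ]
        wins = sub.copy()
        clip_counts = {}
        for c in sorted(cols):
            before = wins[c].to_numpy(dtype=float)
            after = winsorize(before, self.config.winsor_k)
            wins[c] = after
            with np.errstate(invalid="ignore"):
                clip_counts[c] = int(np.nansum(np.abs(after - before) > 0))
        return wins, clip_counts

    def _outcome_correlations(self, wins: pd.DataFrame) -> pd.DataFrame:
        cols = [c for c in OUTCOME_COLUMNS if c in self.config.outcomes]
        mat = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
        for i, a in enumerate(cols):
            for b in cols[i + 1 :]:
                r, _, _ = pearson(wins[a], wins[b])
                mat.loc[a, b] = mat.loc[b, a] = r
        return mat

    def _fit_one(
        self, wins: pd.DataFrame, sample: str, predictor: str, outcome: str
    ) -> list[EffectResult]:
        cfg = self.config
        design_cols = [predictor]
        if cfg.include_attractiveness:
            design_cols.append("attractiveness")
        X = wins[design_cols]
        y = wins[outcome]
        results = standardized_ols(y, X, outcome=outcome)
        if cfg.compute_bayes_factors:
            bf = jzs_bf(y, X, focal=predictor, prior_scale=cfg.bf_prior_scale)
            results = [
                EffectResult(**{**r.as_dict(), "bf10": bf})
                if r.predictor == predictor
                else r
                for r in results
            ]
        return results


def _star(p: float) -> str:
    for cut, s in _STARS:
        if p < cut:
            return s
    return ""


@dataclass
class PaternalInvolvementResults:
    """Fitted estimates, uncertainties, and diagnostics."""

    effects: pd.DataFrame
    correlations: dict
    config: AnalysisConfig
    run_log: list = field(default_factory=list)

    # -------------------------------------------------------- accessors

    def effect_table(self, sample: str, predictor: str) -> pd.DataFrame:
        """Publication-style layout: rows = outcomes, columns = (beta, t) pairs."""
        sub = self.effects[
            (self.effects["sample"] == sample)
            & (self.effects["model_predictor"] == predictor)
        ]
        rows = []
        for outcome in self.config.outcomes:
            block = sub[sub["outcome"] == outcome].set_index("predictor")
            row = {"outcome": outcome}
            for term in block.index:
                row[f"{term}_beta"] = block.loc[term, "beta"]
                row[f"{term}_t"] = block.loc[term, "t"]
                row[f"{term}_sig"] = _star(block.loc[term, "p"])
            rows.append(row)
        return pd.DataFrame(rows)

    def bayes_summary(self) -> pd.DataFrame:
        """Focal-effect Bayes factors across the model grid."""
        focal = self.effects[
            self.effects["predictor"] == self.effects["model_predictor"]
        ]
        return focal[
            ["sample", "model_predictor", "outcome", "beta", "t", "p", "bf10", "n"]
        ].reset_index(drop=True)

    def tables(self) -> dict:
        """All output tables keyed table1..table5 in the canonical order."""
        out = {"table1": self._correlation_table()}
        k = 2
        for predictor in self.config.predictors:
            for sample in self.config.samples:
                out[f"table{k}"] = self.effect_table(sample, predictor)
                k += 1
        out["bayes_factors"] = self.bayes_summary()
        return out

    def _correlation_table(self) -> pd.DataFrame:
        # upper triangle = first sample, lower triangle = second
        samples = list(self.correlations)
        base = self.correlations[samples[0]].copy()
        if len(samples) > 1:
            lower = self.correlations[samples[1]]
            for i, a in enumerate(base.index):
                for b in base.columns[:i]:
                    base.loc[a, b] = lower.loc[a, b]
        return base

    def summary(self) -> str:
        """Human-readable account of every fitted model."""
        lines = ["Paternal involvement analysis", "=" * 31, ""]
        for sample in self.config.samples:
            n = next(
                e["n"] for e in self.run_log
                if e["event"] == "sample" and e["sample"] == sample
            )
            lines.append(f"Sample: {sample} (n = {n})")
            lines.append("-" * 40)
            for predictor in self.config.predictors:
                lines.append(f"  Focal predictor: {predictor}")
                tab = self.effects[
                    (self.effects["sample"] == sample)
                    & (self.effects["model_predictor"] == predictor)
                ]
                for _, r in tab.iterrows():
                    bf = f", BF10 = {r.bf10:.3f}" if np.isfinite(r.bf10 or np.nan) else ""
                    lines.append(
                        f"    {r.outcome:<34s} {r.predictor:<22s} "
                        f"beta = {r.beta:+.3f}, t({r.df}) = {r.t:+.2f}, "
                        f"p = {r.p:.4f}{_star(r.p):<3s}{bf}"
                    )
                lines.append("")
        return "\n".join(lines)

    # ------------------------------------------------------------ export

    def save(self, outdir) -> None:
        """Write table1..table5, bayes_factors.csv and runlog.jsonl."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, tab in self.tables().items():
            tab.to_csv(outdir / f"{name}.csv", index=name == "table1")
        with open(outdir / "runlog.jsonl", "w") as fh:
            fh.write(json.dumps({"event": "config", **asdict(self.config)}) + "\n")
            for entry in self.run_log:
                fh.write(json.dumps(entry) + "\n")


def replicate_from_csv(
    path, config: AnalysisConfig | None = None
) -> PaternalInvolvementResults:
    """Run the standard analysis on an externally supplied table.

    The CSV must follow the analysis-table contract (participant_id,
    is_father, the facial metrics, and the three self-report scores).
    Raises with the list of missing columns on a schema mismatch.  This
    is replication mode: the table is taken as already scored.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"replication table {path} is missing columns: {missing}"
        )
    return PaternalInvolvementModel(df, config).fit()
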