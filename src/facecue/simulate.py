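"""Synthetic study generator with known ground truth.

Emulates the structure of a facial-cue study of paternal involvement:

* 2D landmark configurations (default 131 points) for a male/female
  reference set (49 + 53) and for the participant sample (259 men, 156
  fathers), built as a base face shape displaced along a hidden
  dimorphism direction by a per-face position t_i, plus isotropic
  landmark noise and a random similarity transform per face (so the
  Procrustes stage has real work to do).  Reference females sit around
  t = 0, reference males and participants around t = 1.
* Trait ratings (1-10) from a rater pool (default 422 raters, a small
  fraction flagged as not serious), each rater judging one trait;
  ratings discretise a per-face latent trait plus rater bias and noise.
* Self-report scales (NFS, FIS-involved, FIS-desired) as 1-5 items
  discretising correlated latent scores, with not-applicable entries in
  the FIS items and an exclusion funnel (no photo / low seriousness /
  language / duplicate) injected into the roster.

True standardized effects of the facial predictors on the outcomes are
configurable; the defaults encode zero dimorphism effects and a
negative attractiveness effect on perceived (and desired) involvement.
All randomness flows from ``GeneratorConfig.seed``; the hidden truth
(t_i and all latent traits) is returned for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .landmarks import LandmarkConfiguration, write_tem

__all__ = ["GeneratorConfig", "StudyData", "simulate_study",
           "simulate_analysis_table", "write_study"]

OUTCOMES = ("nfs", "fis_involved", "fis_desired", "perceived_paternal_involvement")


def _default_effects() -> dict:
    # (outcome, predictor) -> true standardized effect.  Dimorphism
    # effects default to zero (null world); attractiveness lowers
    # desired and perceived involvement.
    return {
        ("perceived_paternal_involvement", "attractiveness"): -0.44,
        ("fis_desired", "attractiveness"): -0.13,
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters of the synthetic generator.

    Counts mirror the emulated study; effect sizes are standardized.
    ``landmark_noise_frac`` is the per-coordinate landmark noise SD as
    a fraction of the male-female axis length, so it is also (to first
    order) the SD of the noise on the raw dimorphism score.
    """

    seed: int = 0
    # faces
    n_landmarks: int = 131
    n_ref_female: int = 49
    n_ref_male: int = 53
    n_participants: int = 259
    n_fathers: int = 156
    axis_length: float = 0.05          # sex-difference size, in centroid-size units
    t_spread_ref: float = 0.5          # SD of t within each reference sex
    t_spread_participants: float = 0.5
    landmark_noise_frac: float = 0.10
    # latent trait structure (standardized scales)
    r_attractiveness_dimorphism: float = 0.16
    r_masculinity_dimorphism: float = 0.28
    true_effects: dict = field(default_factory=_default_effects)
    resid_cor_nfs_fisinv: float = 0.6
    resid_cor_fisdes: float = 0.1
    # ratings
    n_raters: int = 422
    rater_sex_probs: tuple = (0.33, 0.57, 0.10)  # male, female, other
    low_seriousness_rate: float = 4 / 422
    ratings_per_face_per_trait: int = 33
    rating_latent_scale: float = 1.5   # rating points per latent SD
    rater_bias_sd: float = 0.5
    rating_noise_sd: float = 1.5
    # self-report items
    item_latent_scale: float = 0.8     # item points per latent SD
    item_noise_sd: float = 0.6
    fis_na_rate: float = 0.10
    # exclusion funnel (counts of extra roster rows per reason)
    exclusion_counts: dict = field(
        default_factory=lambda: {
            "no_photo": 28, "seriousness": 21, "language": 2, "duplicate": 1,
        }
    )

    def with_(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


@dataclass
class StudyData:
    """One complete synthetic study plus its hidden ground truth."""

    ref_female: list
    ref_male: list
    participants: list            # LandmarkConfiguration per kept participant
    ratings: pd.DataFrame         # RatingRecord rows
    selfreports: pd.DataFrame     # roster with item columns and flags
    truth: pd.DataFrame           # per-kept-participant hidden latents
    config: GeneratorConfig


# ---------------------------------------------------------------- faces

def _base_face(n_landmarks: int, rng: np.random.Generator) -> np.ndarray:
    """A vaguely face-like base template: rings of points plus jitter."""
    angles = np.linspace(0, 2 * np.pi, n_landmarks, endpoint=False)
    radii = 1.0 + 0.3 * np.sin(3 * angles) + 0.1 * rng.standard_normal(n_landmarks)
    pts = np.column_stack([radii * np.cos(angles), 1.3 * radii * np.sin(angles)])
    pts -= pts.mean(axis=0)
    pts /= np.sqrt((pts**2).sum())
    return pts


def _dimorphism_direction(base: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Unit direction orthogonal to the similarity group at the base shape.

    Removing the translation, scaling, and infinitesimal-rotation
    components guarantees the Procrustes stage cannot absorb the sex
    difference.
    """
    n = base.shape[0]
    d = rng.standard_normal(base.shape)
    ones = np.ones(n)
    # translation components
    d[:, 0] -= d[:, 0] @ ones / n
    d[:, 1] -= d[:, 1] @ ones / n
    # scaling component (direction of base itself)
    flat_b = base.ravel()
    flat_d = d.ravel()
    flat_d -= (flat_d @ flat_b) / (flat_b @ flat_b) * flat_b
    # infinitesimal rotation at base: (-y, x)
    rot = np.column_stack([-base[:, 1], base[:, 0]]).ravel()
    flat_d -= (flat_d @ rot) / (rot @ rot) * rot
    d = flat_d.reshape(base.shape)
    return d / np.sqrt((d**2).sum())


def _similarity_transform(pts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    theta = rng.uniform(0, 2 * np.pi)
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, -s], [s, c]])
    scale = rng.uniform(80, 400)  # pixels per unit centroid size
    shift = rng.uniform(100, 900, size=2)
    return pts @ R.T * scale + shift


def gen_faces(cfg: GeneratorConfig, rng: np.random.Generator):
    """Reference and participant landmark sets with hidden positions t_i.

    Returns (ref_female, ref_male, participants, truth) where truth is
    a frame with face_id and the generating position t along the
    dimorphism direction (references at 0/1, participants around 1).
    """
    if cfg.n_landmarks < 3:
        raise ValueError("need at least 3 landmarks")
    base = _base_face(cfg.n_landmarks, rng)
    direction = _dimorphism_direction(base, rng)
    noise_sd = cfg.landmark_noise_frac * cfg.axis_length

    def make(face_id: str, t: float) -> LandmarkConfiguration:
        shape = base + t * cfg.axis_length * direction
        shape = shape + rng.normal(0, noise_sd, size=shape.shape)
        return LandmarkConfiguration(face_id, _similarity_transform(shape, rng))

    t_f = rng.normal(0.0, cfg.t_spread_ref, cfg.n_ref_female)
    t_m = rng.normal(1.0, cfg.t_spread_ref, cfg.n_ref_male)
    t_p = rng.normal(1.0, cfg.t_spread_participants, cfg.n_participants)
    ref_female = [make(f"refF{i:03d}", t) for i, t in enumerate(t_f)]
    ref_male = [make(f"refM{i:03d}", t) for i, t in enumerate(t_m)]
    participants = [make(f"p{i:03d}", t) for i, t in enumerate(t_p)]
    truth = pd.DataFrame({
        "face_id": [c.face_id for c in participants],
        "t_true": t_p,
    })
    return ref_female, ref_male, participants, truth


# ----------------------------------------------------- latent structure

def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=1)


def gen_latent_traits(
    cfg: GeneratorConfig, t: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-face latent traits implied by the configured true effects.

    All latents are built on (approximately) unit-variance scales:
    attractiveness and perceived masculinity correlate with the
    standardized dimorphism position at the configured levels; each
    outcome is its linear predictor plus Gaussian residual of
    complementary variance; the three self-report residuals carry the
    configured residual correlations.
    """
    n = t.size
    z = _standardize(t)
    eff = cfg.true_effects

    def corr_with_z(r):
        return r * z + np.sqrt(max(1 - r**2, 0)) * rng.standard_normal(n)

    attr = corr_with_z(cfg.r_attractiveness_dimorphism)
    masc = corr_with_z(cfg.r_masculinity_dimorphism)

    # residuals of the self-report outcomes share correlation structure
    c12, c3 = cfg.resid_cor_nfs_fisinv, cfg.resid_cor_fisdes
    cov = np.array([
        [1.0, c12, c3],
        [c12, 1.0, c3],
        [c3, c3, 1.0],
    ])
    resid3 = rng.multivariate_normal(np.zeros(3), cov, size=n)

    latents = {"dimorphism": z, "attractiveness": attr,
               "perceived_masculinity": masc}
    preds = {"dimorphism": z, "attractiveness": attr}
    for j, outcome in enumerate(("nfs", "fis_involved", "fis_desired")):
        lin = sum(
            eff.get((outcome, p), 0.0) * preds[p] for p in preds
        )
        expl = sum(eff.get((outcome, p), 0.0) ** 2 for p in preds)
        latents[outcome] = lin + np.sqrt(max(1 - expl, 0.05)) * resid3[:, j]
    out = "perceived_paternal_involvement"
    lin = sum(eff.get((out, p), 0.0) * preds[p] for p in preds)
    expl = sum(eff.get((out, p), 0.0) ** 2 for p in preds)
    latents[out] = lin + np.sqrt(max(1 - expl, 0.05)) * rng.standard_normal(n)
    return pd.DataFrame(latents)


# --------------------------------------------------------------- ratings

def gen_ratings(
    cfg: GeneratorConfig,
    face_ids: list,
    latents: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Rating records: rater x face x trait rows on the 1-10 scale."""
    traits = ("attractiveness", "perceived_masculinity",
              "perceived_paternal_involvement")
    n_faces = len(face_ids)
    per_trait = cfg.n_raters // 3
    if per_trait < 1:
        raise ValueError("rater pool too small for 3 traits")
    sexes = rng.choice(
        ["male", "female", "other"], size=cfg.n_raters, p=cfg.rater_sex_probs
    )
    serious = np.where(
        rng.random(cfg.n_raters) < cfg.low_seriousness_rate,
        rng.integers(1, 5, cfg.n_raters),          # 1-4: flagged
        rng.integers(5, 8, cfg.n_raters),          # 5-7: serious
    )
    bias = rng.normal(0, cfg.rater_bias_sd, cfg.n_raters)

    rows = []
    rater_idx = np.arange(cfg.n_raters)
    for k, trait in enumerate(traits):
        pool = rater_idx[k::3]
        if cfg.ratings_per_face_per_trait > pool.size:
            raise ValueError(
                f"{cfg.ratings_per_face_per_trait} ratings/face requested but "
                f"only {pool.size} raters assigned to {trait}"
            )
        latent = latents[trait].to_numpy()
        for i in range(n_faces):
            chosen = rng.choice(pool, cfg.ratings_per_face_per_trait, replace=False)
            vals = (
                5.5
                + cfg.rating_latent_scale * latent[i]
                + bias[chosen]
                + rng.normal(0, cfg.rating_noise_sd, chosen.size)
            )
            vals = np.clip(np.rint(vals), 1, 10).astype(int)
            rows.append(pd.DataFrame({
                "rater_id": [f"r{j:03d}" for j in chosen],
                "face_id": face_ids[i],
                "trait": trait,
                "value": vals,
                "rater_sex": sexes[chosen],
                "seriousness": serious[chosen],
            }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------- self-reports

def _discretize_items(
    latent: np.ndarray, n_items: int, cfg: GeneratorConfig,
    rng: np.random.Generator, allow_na: bool,
) -> np.ndarray:
    vals = (
        3.0
        + cfg.item_latent_scale * latent[:, None]
        + rng.normal(0, cfg.item_noise_sd, (latent.size, n_items))
    )
    vals = np.clip(np.rint(vals), 1, 5)
    if allow_na:
        vals[rng.random(vals.shape) < cfg.fis_na_rate] = np.nan
    return vals


def gen_self_reports(
    cfg: GeneratorConfig,
    face_ids: list,
    latents: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Roster of self-report responses with injected exclusion flags.

    The kept participants (those passing the funnel) carry the supplied
    latent outcome scores; extra roster rows, one block per exclusion
    reason, are appended with flags set so the funnel removes exactly
    the configured counts.  A duplicate participant contributes TWO
    roster rows (the original and the repeat submission) sharing one
    id, both flagged and both removed — so ``duplicate: 1`` adds two
    rows to the roster.
    """
    n_kept = len(face_ids)
    row_counts = dict(cfg.exclusion_counts)
    row_counts["duplicate"] = 2 * row_counts.get("duplicate", 0)
    n_extra = sum(row_counts.values())
    ids_kept = [f"{fid}" for fid in face_ids]
    ids_extra = [f"x{i:03d}" for i in range(n_extra)]
    # repeat submissions share the id of their first record
    n_dup = row_counts["duplicate"]
    if n_dup:
        firsts = ids_extra[-n_dup::2]
        ids_extra[-n_dup:] = [fid for fid in firsts for _ in range(2)]
    all_ids = ids_kept + ids_extra
    n_total = len(all_ids)

    # latent outcomes: kept rows use the supplied latents, extras fresh
    lat = {}
    for col in ("nfs", "fis_involved", "fis_desired"):
        extra = rng.standard_normal(n_extra)
        lat[col] = np.concatenate([latents[col].to_numpy(), extra])

    nfs_items = _discretize_items(lat["nfs"], 9, cfg, rng, allow_na=False)
    fisr_items = _discretize_items(lat["fis_involved"], 20, cfg, rng, allow_na=True)
    fisd_items = _discretize_items(lat["fis_desired"], 20, cfg, rng, allow_na=True)

    df = pd.DataFrame({"participant_id": all_ids})
    for j in range(9):
        df[f"nfs_{j+1}"] = nfs_items[:, j]
    for j in range(20):
        df[f"fisR_{j+1}"] = fisr_items[:, j]
    for j in range(20):
        df[f"fisD_{j+1}"] = fisd_items[:, j]

    # flags: kept rows are clean; one block of extras per reason
    df["has_photo"] = True
    df["seriousness"] = rng.integers(5, 8, n_total)
    df["language_issue"] = False
    df["duplicate"] = False
    pos = n_kept
    for reason, count in row_counts.items():
        idx = slice(pos, pos + count)
        if reason == "no_photo":
            df.loc[df.index[idx], "has_photo"] = False
        elif reason == "seriousness":
            df.loc[df.index[idx], "seriousness"] = rng.integers(1, 5, count)
        elif reason == "language":
            df.loc[df.index[idx], "language_issue"] = True
        elif reason == "duplicate":
            df.loc[df.index[idx], "duplicate"] = True
        else:
            raise ValueError(f"unknown exclusion reason {reason!r}")
        pos += count

    # father status among kept participants
    fathers = rng.choice(n_kept, size=min(cfg.n_fathers, n_kept), replace=False)
    is_father = np.zeros(n_total, dtype=bool)
    is_father[fathers] = True
    df["is_father"] = is_father
    # shuffle roster order so exclusions are not positionally trivial
    perm = rng.permutation(n_total)
    return df.iloc[perm].reset_index(drop=True)


# ------------------------------------------------------------ top level

def simulate_study(cfg: GeneratorConfig | None = None) -> StudyData:
    """Generate one full synthetic study (faces, ratings, self-reports)."""
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    ref_f, ref_m, participants, truth = gen_faces(cfg, rng)
    latents = gen_latent_traits(cfg, truth["t_true"].to_numpy(), rng)
    latents.insert(0, "face_id", truth["face_id"].to_numpy())
    face_ids = list(truth["face_id"])
    ratings = gen_ratings(cfg, face_ids, latents, rng)
    selfreports = gen_self_reports(cfg, face_ids, latents, rng)
    truth = truth.merge(latents, on="face_id")
    return StudyData(
        ref_female=ref_f, ref_male=ref_m, participants=participants,
        ratings=ratings, selfreports=selfreports, truth=truth, config=cfg,
    )


def simulate_analysis_table(
    cfg: GeneratorConfig | None = None, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Analysis-ready per-participant table, skipping the landmark stage.

    Uses the same latent-trait model as :func:`simulate_study` but
    replaces the geometry with its statistical equivalent: the raw
    dimorphism score is the hidden position t_i plus Gaussian noise of
    SD ``landmark_noise_frac`` (the score noise the landmark noise
    induces), and rating means are generated directly.  Intended for
    many-replicate calibration studies where landmark generation and
    Procrustes alignment — deterministic, separately validated steps —
    would dominate the runtime.
    """
    cfg = cfg or GeneratorConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_participants
    t = rng.normal(1.0, cfg.t_spread_participants, n)
    latents = gen_latent_traits(cfg, t, rng)

    score = t + rng.normal(0, cfg.landmark_noise_frac, n)

    m = cfg.ratings_per_face_per_trait
    noise_sd = np.hypot(cfg.rater_bias_sd, cfg.rating_noise_sd)
    means = {}
    for trait in ("attractiveness", "perceived_masculinity",
                  "perceived_paternal_involvement"):
        vals = (
            5.5
            + cfg.rating_latent_scale * latents[trait].to_numpy()[:, None]
            + rng.normal(0, noise_sd, (n, m))
        )
        means[trait] = np.clip(np.rint(vals), 1, 10).mean(axis=1)

    nfs = _discretize_items(latents["nfs"].to_numpy(), 9, cfg, rng, False)
    fisr = _discretize_items(latents["fis_involved"].to_numpy(), 20, cfg, rng, True)
    fisd = _discretize_items(latents["fis_desired"].to_numpy(), 20, cfg, rng, True)

    fathers = rng.choice(n, size=min(cfg.n_fathers, n), replace=False)
    is_father = np.zeros(n, dtype=bool)
    is_father[fathers] = True

    with np.errstate(invalid="ignore"):
        return pd.DataFrame({
            "participant_id": [f"p{i:03d}" for i in range(n)],
            "is_father": is_father,
            "objective_dimorphism": score,
            "attractiveness": means["attractiveness"],
            "perceived_masculinity": means["perceived_masculinity"],
            "perceived_paternal_involvement":
                means["perceived_paternal_involvement"],
            "nfs": np.nanmean(nfs, axis=1),
            "fis_involved": np.nanmean(fisr, axis=1),
            "fis_desired": np.nanmean(fisd, axis=1),
            "t_true": t,
        })


def write_study(study: StudyData, outdir) -> None:
    """Write a study to disk: TEM landmark files plus CSV tables."""
    outdir = Path(outdir)
    for sub, faces in [
        ("ref_female", study.ref_female),
        ("ref_male", study.ref_male),
        ("participants", study.participants),
    ]:
        d = outdir / sub
        d.mkdir(parents=True, exist_ok=True)
        for cfg_face in faces:
            write_tem(cfg_face, d / f"{cfg_face.face_id}.tem")
    study.ratings.to_csv(outdir / "ratings.csv", index=False)
    study.selfreports.to_csv(outdir / "selfreports.csv", index=False)
    study.truth.to_csv(outdir / "truth.csv", index=False)
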