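"""Synthetic cohort generator with planted, recoverable effects.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage of the pipeline is testable without any private
data:

* a latent well-being scalar per user drawn from a Beta distribution
  skewed low (a high-risk sample); SWLS and WHO-5 are correlated noisy
  transforms of it targeting a configurable inter-scale correlation
  (default 0.568);
* private-message lemma streams over the 365 days before each user's
  reference time, mixing a Zipf-weighted neutral vocabulary, sentiment
  words whose rate is modulated by latent well-being, and planted-effect
  words; alters are allocated by a Dirichlet-multinomial;
* one observation week of app-usage sessions whose night-time (0-6 h)
  share shifts with WHO-5 by a configurable circadian effect;
* PHQ-9 / GAD / PSS screening scores that decrease noisily and
  monotonically in WHO-5, anchored so the conditional questionnaire mean
  equals its screen-positive threshold at WHO-5(norm) = 0.51.

Everything is a deterministic function of the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .apps import CATEGORIES, AppCategoryMap
from .records import AppUsageEvent, Cohort, MessageEvent, UserRecord
from .text import CATEGORY_TAGS, Lexicon

__all__ = [
    "ConfigError",
    "CohortConfig",
    "generate_cohort",
    "generate_messages",
    "generate_usage",
    "generate_mh_scores",
    "latent_swb",
    "synthetic_sentiment_lexicon",
    "synthetic_category_lexicon",
    "synthetic_app_map",
    "write_cohort",
    "read_cohort",
]

SECONDS_PER_DAY = 86400
MESSAGE_WINDOW_DAYS = 365


class ConfigError(ValueError):
    """Invalid cohort configuration; the message names the field."""


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort.

    The defaults are the study conditions the pipeline targets: skewed-low
    well-being with inter-scale correlation 0.568, a 365-day message
    window, a 7-day usage window, and screening-score links anchored at
    the 0.51 normalized WHO-5 cutoff.
    """

    n_users: int = 372
    seed: int = 0
    #: target Pearson correlation between the two normalized scales
    scale_corr: float = 0.568
    #: mean / sd of the latent Beta well-being distribution
    swb_location: float = 0.45
    swb_spread: float = 0.155
    vocab_size: int = 500
    n_sentiment_words: int = 60
    #: word -> signed effect size on latent well-being
    planted_word_effects: dict = field(default_factory=lambda: {
        "planted_up_a": 0.8, "planted_up_b": 0.5,
        "planted_down_a": -0.8, "planted_down_b": -0.5,
    })
    #: mean messages per user over the 365-day window
    message_rate: float = 400.0
    tokens_per_message: float = 6.0
    n_alters_mean: float = 8.0
    app_categories: tuple = CATEGORIES
    #: signed effect of (0.5 - who5_norm) on the night-slot usage share
    circadian_effect: float = 0.15
    #: sd of the Gaussian noise linking WHO-5 to PHQ/GAD/PSS
    mh_noise: float = 5.0
    #: probability that each questionnaire is missing for a user
    mh_missing_rate: float = 0.17
    #: base probability of a planted word per token
    planted_base_rate: float = 0.004
    negative_sentiment_base: float = 0.06
    negative_sentiment_effect: float = 0.03
    positive_sentiment_base: float = 0.05
    positive_sentiment_effect: float = 0.015
    night_share_base: float = 0.08
    observation_days: int = 7
    usage_sessions_per_week: float = 150.0
    base_time: str = "2021-06-01"

    def __post_init__(self) -> None:
        if self.n_users < 0:
            raise ConfigError("n_users must be >= 0")
        if not -1.0 < self.scale_corr < 1.0:
            raise ConfigError("scale_corr must lie in (-1, 1)")
        if not 0.0 < self.swb_location < 1.0:
            raise ConfigError("swb_location must lie in (0, 1)")
        if self.swb_spread <= 0 or (self.swb_spread ** 2
                                    >= self.swb_location
                                    * (1 - self.swb_location)):
            raise ConfigError("swb_spread incompatible with swb_location "
                              "for a Beta distribution")
        for name in ("message_rate", "n_alters_mean", "mh_noise",
                     "usage_sessions_per_week", "planted_base_rate",
                     "tokens_per_message"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if len(self.app_categories) != 9:
            raise ConfigError("app_categories must list exactly 9 labels")
        if self.observation_days < 0:
            raise ConfigError("observation_days must be >= 0")
        if not 0 <= self.mh_missing_rate < 1:
            raise ConfigError("mh_missing_rate must lie in [0, 1)")
        if self.vocab_size < 1:
            raise ConfigError("vocab_size must be >= 1")
        if self.n_sentiment_words < 2 or self.n_sentiment_words % 2:
            raise ConfigError("n_sentiment_words must be an even count >= 2")

    # --- derived vocabulary pieces -------------------------------------
    @property
    def neutral_words(self) -> list[str]:
        return [f"w{i:04d}" for i in range(self.vocab_size)]

    @property
    def positive_words(self) -> list[str]:
        return [f"pos{i:03d}" for i in range(self.n_sentiment_words // 2)]

    @property
    def negative_words(self) -> list[str]:
        return [f"neg{i:03d}" for i in range(self.n_sentiment_words // 2)]

    @property
    def planted_words(self) -> list[str]:
        return list(self.planted_word_effects)


def latent_swb(config: CohortConfig, n: int, rng: np.random.Generator
               ) -> np.ndarray:
    """Latent well-being draws from the skewed-low Beta distribution."""
    loc, sd = config.swb_location, config.swb_spread
    conc = loc * (1 - loc) / sd ** 2 - 1
    return rng.beta(loc * conc, (1 - loc) * conc, size=n)


def _observed_scales(z: np.ndarray, config: CohortConfig,
                     rng: np.random.Generator):
    """Two correlated noisy transforms of the latent score, on [0, 1]."""
    r = config.scale_corr
    if r > 0:
        z2 = z
    elif r == 0:
        z2 = latent_swb(config, z.size, rng)
    else:  # mirror the latent around its location for a negative link
        z2 = np.clip(2 * config.swb_location - z, 0.0, 1.0)
    if r != 0:
        sigma_e = config.swb_spread * np.sqrt((1 - abs(r)) / abs(r))
    else:
        sigma_e = config.swb_spread * 0.5
    who5 = np.clip(z + rng.normal(0, sigma_e, z.size), 0.0, 1.0)
    swls = np.clip(z2 + rng.normal(0, sigma_e, z.size), 0.0, 1.0)
    return swls, who5


def generate_mh_scores(who5_norm: float, config: CohortConfig,
                       rng: np.random.Generator):
    """Noisy monotone-decreasing screening scores given normalized WHO-5.

    Conditional means are anchored so each questionnaire hits its
    screen-positive threshold (PHQ 10, GAD 10, PSS 21) exactly at
    WHO-5(norm) = 0.51; results are rounded and clipped to each scale's
    range.
    """
    if not 0.0 <= who5_norm <= 1.0:
        raise ValueError("who5_norm must lie in [0, 1]")
    d = 0.51 - who5_norm
    noise = config.mh_noise
    phq = 10 + 24 * d + rng.normal(0, noise)
    gad = 10 + 20 * d + rng.normal(0, 0.9 * noise)
    pss = 21 + 30 * d + rng.normal(0, 1.2 * noise)
    return (int(np.clip(round(phq), 0, 27)),
            int(np.clip(round(gad), 0, 21)),
            int(np.clip(round(pss), 0, 40)))


def _user_z_std(user: UserRecord, config: CohortConfig) -> float:
    """Standardized latent-SWB proxy from the user's observed scales."""
    swls_norm = (user.swls_raw - 5) / 30.0
    who5_norm = (user.who5_raw - 5) / 25.0
    return ((swls_norm + who5_norm) / 2 - config.swb_location) \
        / config.swb_spread


def _token_distribution(config: CohortConfig, z_std: float):
    """Per-token word probabilities for one user."""
    planted = config.planted_words
    p_planted = np.array([
        config.planted_base_rate * max(0.0, 1.0 + eff * z_std)
        for eff in config.planted_word_effects.values()])
    p_neg = float(np.clip(config.negative_sentiment_base
                          - config.negative_sentiment_effect * z_std,
                          0.002, 0.5))
    p_pos = float(np.clip(config.positive_sentiment_base
                          + config.positive_sentiment_effect * z_std,
                          0.002, 0.5))
    n_half = config.n_sentiment_words // 2
    zipf = 1.0 / (np.arange(config.vocab_size) + 2.0)
    p_neutral_mass = max(0.0, 1.0 - p_neg - p_pos - p_planted.sum())
    probs = np.concatenate([
        zipf / zipf.sum() * p_neutral_mass,
        np.full(n_half, p_pos / n_half),
        np.full(n_half, p_neg / n_half),
        p_planted,
    ])
    words = (config.neutral_words + config.positive_words
             + config.negative_words + planted)
    return words, probs / probs.sum()


def generate_messages(user: UserRecord, config: CohortConfig,
                      rng: np.random.Generator) -> list[MessageEvent]:
    """One user's message stream over the 365 days before reference time.

    Message days follow an inhomogeneous (sinusoidally modulated) daily
    rate; alters are allocated by a Dirichlet-multinomial so alter counts
    vary across users and months.
    """
    if config.message_rate == 0:
        return []
    n_msgs = int(rng.poisson(config.message_rate))
    if n_msgs == 0:
        return []
    ref = user.reference_time

    # inhomogeneous daily intensity across the year
    days = np.arange(MESSAGE_WINDOW_DAYS)
    day_w = 1.0 + 0.3 * np.sin(2 * np.pi * days / MESSAGE_WINDOW_DAYS)
    day_w /= day_w.sum()
    msg_days = rng.choice(MESSAGE_WINDOW_DAYS, size=n_msgs, p=day_w)
    within = rng.uniform(0, SECONDS_PER_DAY, size=n_msgs)
    offsets = msg_days * SECONDS_PER_DAY + within  # seconds back from ref

    n_alters = max(1, int(rng.poisson(config.n_alters_mean)))
    alter_w = rng.dirichlet(np.full(n_alters, 0.7))
    alter_ids = rng.choice(n_alters, size=n_msgs, p=alter_w)

    lengths = 1 + rng.poisson(max(0.0, config.tokens_per_message - 1),
                              size=n_msgs)
    words, probs = _token_distribution(config, _user_z_std(user, config))
    tokens = rng.choice(len(words), size=int(lengths.sum()), p=probs)
    boundaries = np.cumsum(lengths)[:-1]
    token_runs = np.split(tokens, boundaries)

    events = []
    for i in range(n_msgs):
        ts = ref - pd.Timedelta(seconds=float(offsets[i]))
        events.append(MessageEvent(
            user_id=user.user_id,
            alter_id=f"{user.user_id}-a{alter_ids[i]:03d}",
            timestamp=ts,
            tokens=[words[j] for j in token_runs[i]],
        ))
    return events


_CAT_SLUGS = {c: c.lower().replace("+", "_") for c in CATEGORIES}
#: package-draw weights over the nine categories (social-heavy, as in
#: messenger-centric phone use)
_CAT_WEIGHTS = np.array([0.10, 0.10, 0.12, 0.12, 0.05, 0.03,
                         0.35, 0.08, 0.05])
_PACKAGES_PER_CATEGORY = 20


def synthetic_app_map(config: CohortConfig | None = None,
                      packages_per_category: int = _PACKAGES_PER_CATEGORY
                      ) -> AppCategoryMap:
    """Category map covering every package name the generator can emit."""
    mapping = {}
    for cat in CATEGORIES:
        slug = _CAT_SLUGS[cat]
        for i in range(packages_per_category):
            mapping[f"app.{slug}.{i:03d}"] = cat
    return AppCategoryMap(mapping)


def generate_usage(user: UserRecord, config: CohortConfig,
                   rng: np.random.Generator) -> list[AppUsageEvent]:
    """One observation window of foreground sessions for one user.

    Start hours come from a two-component circadian mixture: a night
    component uniform on [0, 6) h whose share grows as WHO-5 falls (by
    ``circadian_effect``), and a day component uniform on [6, 24) h.
    """
    if config.observation_days == 0:
        return []
    rate = config.usage_sessions_per_week * config.observation_days / 7.0
    n = int(rng.poisson(rate))
    if n == 0:
        return []
    who5_norm = (user.who5_raw - 5) / 25.0
    night_p = float(np.clip(
        config.night_share_base
        + config.circadian_effect * (0.5 - who5_norm), 0.01, 0.9))
    day_idx = rng.integers(0, config.observation_days, size=n)
    is_night = rng.random(n) < night_p
    # wall-clock second of day from the circadian mixture
    sod = np.where(is_night,
                   rng.uniform(0, 6 * 3600, size=n),
                   rng.uniform(6 * 3600, 24 * 3600, size=n))
    durations = np.maximum(
        1, np.round(rng.lognormal(np.log(20.0), 1.0, size=n) * 1000)
    ).astype(int)
    cats = rng.choice(len(CATEGORIES), size=n, p=_CAT_WEIGHTS)
    pkg_idx = rng.integers(0, _PACKAGES_PER_CATEGORY, size=n)
    # anchor to midnight so the mixture is a true wall-clock pattern; a
    # candidate before the consent instant wraps to the window's last day
    ref = user.reference_time
    midnight = ref.normalize()
    window_s = config.observation_days * SECONDS_PER_DAY
    events = []
    for i in range(n):
        slug = _CAT_SLUGS[CATEGORIES[cats[i]]]
        offset = float(day_idx[i] * SECONDS_PER_DAY + sod[i])
        start = midnight + pd.Timedelta(seconds=offset)
        if start < ref:
            start += pd.Timedelta(seconds=window_s)
        events.append(AppUsageEvent(
            user_id=user.user_id,
            package=f"app.{slug}.{pkg_idx[i]:03d}",
            start=start,
            duration_ms=int(durations[i]),
        ))
    return events


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate users plus message and usage streams; deterministic in
    ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_users
    if n == 0:
        return Cohort(users=[], messages=[], usage=[],
                      swls_items=np.zeros((0, 5)),
                      who5_items=np.zeros((0, 5)))

    z = latent_swb(config, n, rng)
    swls_norm, who5_norm = _observed_scales(z, config, rng)
    swls_raw = np.clip(np.round(5 + 30 * swls_norm), 5, 35).astype(int)
    who5_raw = np.clip(np.round(5 + 25 * who5_norm), 5, 30).astype(int)

    ages = np.clip(np.round(rng.normal(23, 5, n)), 18, 53).astype(int)
    genders = np.where(rng.random(n) < 0.8, "female", "male")
    friends = np.round(rng.lognormal(np.log(150), 0.8, n)).astype(int)
    subs = np.round(rng.lognormal(np.log(80), 0.9, n)).astype(int)
    base = pd.Timestamp(config.base_time)
    ref_offsets = rng.uniform(0, 30 * SECONDS_PER_DAY, n)

    # item-level scores: raw total split by a symmetric Dirichlet
    swls_items = 1 + (swls_raw - 5)[:, None] * rng.dirichlet(np.full(5, 8.0), n)
    who5_items = 1 + (who5_raw - 5)[:, None] * rng.dirichlet(np.full(5, 8.0), n)

    users = []
    for i in range(n):
        w5n = (who5_raw[i] - 5) / 25.0
        phq, gad, pss = generate_mh_scores(float(w5n), config, rng)
        miss = rng.random(3) < config.mh_missing_rate
        users.append(UserRecord(
            user_id=f"u{i:05d}",
            age=int(ages[i]), gender=str(genders[i]),
            n_vk_friends=int(friends[i]), n_subscriptions=int(subs[i]),
            swls_raw=int(swls_raw[i]), who5_raw=int(who5_raw[i]),
            phq=None if miss[0] else phq,
            gad=None if miss[1] else gad,
            pss=None if miss[2] else pss,
            reference_time=base + pd.Timedelta(
                seconds=round(float(ref_offsets[i]))),
        ))

    messages: list[MessageEvent] = []
    usage: list[AppUsageEvent] = []
    for u in users:
        messages.extend(generate_messages(u, config, rng))
        usage.extend(generate_usage(u, config, rng))
    return Cohort(users=users, messages=messages, usage=usage,
                  swls_items=swls_items, who5_items=who5_items)


def synthetic_sentiment_lexicon(config: CohortConfig) -> Lexicon:
    entries = {w: "positive" for w in config.positive_words}
    entries.update({w: "negative" for w in config.negative_words})
    return Lexicon(entries)


def synthetic_category_lexicon(config: CohortConfig) -> Lexicon:
    """Deterministic 8-category lexicon over a third of the neutral words."""
    entries = {}
    for i, w in enumerate(config.neutral_words):
        if i % 3 == 0:
            entries[w] = CATEGORY_TAGS[(i // 3) % len(CATEGORY_TAGS)]
    return Lexicon(entries)


# --- plain-text writers / readers --------------------------------------

USERS_HEADER = ["user_id", "age", "gender", "n_vk_friends",
                "n_subscriptions", "swls_raw", "who5_raw",
                "phq", "gad", "pss", "reference_time"]


def write_cohort(cohort: Cohort, outdir) -> dict[str, Path]:
    """Write users.csv, messages.jsonl and app_usage.csv under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "users": outdir / "users.csv",
        "messages": outdir / "messages.jsonl",
        "usage": outdir / "app_usage.csv",
    }
    df = cohort.users_frame()
    df["reference_time"] = df["reference_time"].map(
        lambda t: t.isoformat())
    for c in ("phq", "gad", "pss"):
        df[c] = df[c].astype("Int64")
    df.to_csv(paths["users"], index=False, columns=USERS_HEADER)
    with open(paths["messages"], "w", encoding="utf-8") as fh:
        for m in cohort.messages:
            fh.write(json.dumps({
                "user": m.user_id, "alter": m.alter_id,
                "timestamp": m.timestamp.isoformat(),
                "tokens": m.tokens,
            }) + "\n")
    pd.DataFrame(
        [{"user_id": e.user_id, "package": e.package,
          "start": e.start.isoformat(), "duration_ms": e.duration_ms}
         for e in cohort.usage]
    ).to_csv(paths["usage"], index=False)
    return paths


def read_cohort(outdir) -> Cohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    outdir = Path(outdir)
    df = pd.read_csv(outdir / "users.csv")
    users = []
    for _, r in df.iterrows():
        users.append(UserRecord(
            user_id=str(r["user_id"]), age=int(r["age"]),
            gender=str(r["gender"]), n_vk_friends=int(r["n_vk_friends"]),
            n_subscriptions=int(r["n_subscriptions"]),
            swls_raw=int(r["swls_raw"]), who5_raw=int(r["who5_raw"]),
            phq=None if pd.isna(r["phq"]) else int(r["phq"]),
            gad=None if pd.isna(r["gad"]) else int(r["gad"]),
            pss=None if pd.isna(r["pss"]) else int(r["pss"]),
            reference_time=pd.Timestamp(r["reference_time"]),
        ))
    messages = []
    msg_path = outdir / "messages.jsonl"
    if msg_path.exists():
        with open(msg_path, encoding="utf-8") as fh:
            for line in fh:
                d = json.loads(line)
                messages.append(MessageEvent(
                    user_id=d["user"], alter_id=d["alter"],
                    timestamp=pd.Timestamp(d["timestamp"]),
                    tokens=list(d["tokens"])))
    usage = []
    usage_path = outdir / "app_usage.csv"
    if usage_path.exists():
        udf = pd.read_csv(usage_path)
        for _, r in udf.iterrows():
            usage.append(AppUsageEvent(
                user_id=str(r["user_id"]), package=str(r["package"]),
                start=pd.Timestamp(r["start"]),
                duration_ms=int(r["duration_ms"])))
    return Cohort(users=users, messages=messages, usage=usage)
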