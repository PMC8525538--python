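"""Seeded synthetic communities with known ground truth.

The generator emulates the two datasets the analysis needs:

* a volunteer questionnaire pool (profile tables linked to SAS index
  scores through a documented linear link plus configurable noise), and
* topic-based communities: a follower graph with high-in-degree influencer
  accounts, members with latent anxiety in [0, 1], and pseudo-text messages
  whose anxiety-anchor density, topic-word density and readability features
  carry the latent signals.

Three community-level effects are wired in and recoverable downstream:

* ``effect_proximity``  — additive shift of mean latent anxiety for
  proximate topics, realized through member composition: who joins the
  community is tilted along the profile anxiety link, so the shift is
  visible to the profile factor and, via the latent level, to the topical
  factor;
* ``effect_dk``         — slope of latent anxiety on the community's
  declarative-knowledge level, split half composition / half topical
  expression (the knowledge level also drives credible sources, topic-word
  density and readability);
* ``effect_influencer_sd`` — slope of the community's day-to-day mood
  noise scale on its influencer fraction (mood is a random walk added to
  the anchor-emission propensity of each day's messages).

All members are active from day 0 (hashtag-burst onboarding), so the daily
collective-anxiety series measures mood-driven fluctuation rather than a
membership ramp; later messages, reposts and comments spread uniformly
over the rest of the window.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from ._wordlists import ANXIETY_ANCHORS, CLAUSE_MARKERS, PERSONAL_PRONOUNS, STOPWORDS
from .embeddings import WordEmbedding
from .lexicon import AnchorLexicon, FrequencyLexicon
from .scoring import SAS_MAX, SAS_MIN, band_sas_score
from .stats import rate_community

__all__ = [
    "SyntheticConfig", "TopicCommunity", "LatentTruth", "Corpus",
    "generate_sas_training", "generate_community", "generate_corpus",
    "profile_anxiety_link", "TOPIC_FIELDS", "build_frequency_lexicon",
    "build_embedding",
]

TOPIC_FIELDS = ("art", "education", "entertainment", "movietv",
                "publicaffairs", "sports")

_GENDERS = ("female", "male", "other")
_OCCUPATIONS = ("clerical", "manual", "professional", "retired", "service", "student")
_LOCATIONS = ("central", "east", "north", "northeast", "south", "west")

# Additive effects of the categorical profile features on the latent link.
_GENDER_EFF = {"female": 0.02, "male": -0.02, "other": 0.0}
_OCC_EFF = dict(zip(_OCCUPATIONS, (-0.03, -0.018, -0.006, 0.006, 0.018, 0.03)))
_LOC_EFF = dict(zip(_LOCATIONS, (-0.01, -0.006, -0.002, 0.002, 0.006, 0.01)))
_AGE_COEF = -0.008     # per year away from 40
_EDU_COEF = -0.03      # per education level away from 3
_INC_COEF = -0.025     # per income band away from 3
_LINK_BASE = 0.35


def _pseudo_words(n: int, rng: np.random.Generator, taken: set[str]) -> list[str]:
    cons, vow = "bdfgklmnprstvz", "aeiou"
    words: list[str] = []
    while len(words) < n:
        k = rng.integers(2, 4)
        w = "".join(cons[rng.integers(len(cons))] + vow[rng.integers(len(vow))]
                    for _ in range(k))
        if w not in taken:
            taken.add(w)
            words.append(w)
    return words


def _build_vocabulary():
    taken = set(STOPWORDS) | set(ANXIETY_ANCHORS) | set(TOPIC_FIELDS)
    rng = np.random.default_rng(7)
    neutral = _pseudo_words(200, rng, taken)
    rare = _pseudo_words(80, rng, taken)
    topic = {f: _pseudo_words(12, rng, taken) for f in TOPIC_FIELDS}
    return neutral, rare, topic


#: Fixed synthetic vocabulary, identical across corpora.
NEUTRAL_WORDS, RARE_WORDS, TOPIC_WORDS = _build_vocabulary()


def build_frequency_lexicon() -> FrequencyLexicon:
    """Corpus word-frequency list.  Rare words are deliberately absent, so
    they count as "difficult" for the readability features."""
    counts: dict[str, int] = {}
    for i, w in enumerate(sorted(STOPWORDS)):
        counts[w] = 50_000 - 100 * i
    for i, w in enumerate(NEUTRAL_WORDS):
        counts[w] = int(20_000 / (i + 2))
    for f in TOPIC_FIELDS:
        counts[f] = 1_500
        for w in TOPIC_WORDS[f]:
            counts[w] = 700
    for w in ANXIETY_ANCHORS:
        counts[w] = 900
    ordered = dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
    return FrequencyLexicon(ordered)


def build_embedding(dim: int, seed: int) -> WordEmbedding:
    """Structured word vectors: anchors form one cluster, each field's topic
    words cluster around the field label, everything else is random."""
    rng = np.random.default_rng([seed, 2])

    def unit(v):
        return v / np.linalg.norm(v)

    vecs: dict[str, np.ndarray] = {}
    anchor_center = unit(rng.standard_normal(dim))
    for w in ANXIETY_ANCHORS:
        vecs[w] = unit(anchor_center + 0.33 * rng.standard_normal(dim))
    for f in TOPIC_FIELDS:
        label = unit(rng.standard_normal(dim))
        vecs[f] = label
        for w in TOPIC_WORDS[f]:
            vecs[w] = unit(label + 0.5 * rng.standard_normal(dim))
    for w in (*NEUTRAL_WORDS, *RARE_WORDS, *PERSONAL_PRONOUNS, *CLAUSE_MARKERS):
        vecs[w] = unit(rng.standard_normal(dim))
    return WordEmbedding(vecs)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a synthetic corpus.

    Effects are wired as documented in the module docstring; sizes, window
    and community count default to the desk-scale study conditions
    (200 communities of 50-500 members over a 28-day window).
    """

    n_communities: int = 200
    size_range: tuple[int, int] = (50, 500)
    influencer_fraction: float = 0.2     # mean; per community ~ U(0, 2x), capped at 1
    messages_per_user_mean: float = 4.0  # including the day-0 onboarding post
    effect_proximity: float = -0.2
    effect_dk: float = -0.5
    effect_influencer_sd: float = -0.1
    noise_sd: float = 0.05               # day-mood random-walk step SD (latent units)
    n_days: int = 28
    embedding_dim: int = 128
    seed: int = 0
    # secondary shape parameters
    community_sd: float = 0.18           # community base-anxiety SD
    member_sd: float = 0.15              # member idiosyncratic latent SD
    anchor_slope: float = 8.0            # logistic slope of anchor emission in latent
    mood_gain: float = 2.0               # amplification of day mood in anchor emission
    mean_out_degree: float = 3.0         # follower out-degree mean
    influencer_fitness: float = 8.0      # in-degree attractiveness multiplier
    verified_fraction: float = 0.08      # institution-verified personal accounts
    arrival_decay_days: float = 0.0      # decay scale of later messages; <=0 = uniform

    def __post_init__(self):
        lo, hi = self.size_range
        if lo < 3 or hi < lo:
            raise ValueError("size_range must satisfy 3 <= min <= max")
        for name in ("influencer_fraction", "verified_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.messages_per_user_mean <= 0 or self.noise_sd <= 0:
            raise ValueError("messages_per_user_mean and noise_sd must be positive")
        if self.n_days < 2:
            raise ValueError("n_days must be >= 2")
        if self.n_communities < 1:
            raise ValueError("n_communities must be >= 1")
        if self.embedding_dim < 2:
            raise ValueError("embedding_dim must be >= 2")


@dataclass
class TopicCommunity:
    community_id: str
    field: str
    familiarity: int
    proximity: int
    profiles: pd.DataFrame
    messages: pd.DataFrame
    edges: pd.DataFrame        # directed follower edges (src, dst)


@dataclass
class LatentTruth:
    community_id: str
    user_latent: pd.Series     # latent anxiety in [0,1], indexed by user_id
    true_mean: float
    true_rating: str           # 5-level band of the true mean
    dk_wired: float
    influencer_fraction_wired: float
    mood_sigma: float
    base_shift: float


@dataclass
class Corpus:
    profiles: pd.DataFrame
    messages: pd.DataFrame
    edges: pd.DataFrame
    communities: pd.DataFrame
    truth: pd.DataFrame
    user_truth: pd.DataFrame
    sas_profiles: pd.DataFrame
    sas_records: pd.DataFrame
    embedding: WordEmbedding
    word_freq: FrequencyLexicon
    manifest: dict

    @property
    def anchor_lexicon(self) -> AnchorLexicon:
        return AnchorLexicon()


def _draw_profiles(rng: np.random.Generator, n: int, prefix: str,
                   comp_shift: float = 0.0, influencer_fraction: float = 0.0,
                   verified_fraction: float = 0.0) -> pd.DataFrame:
    """Profile table; ``comp_shift`` tilts who joins the community.

    Each member is picked from three candidate profiles as the one whose
    anxiety link lies closest to a member-specific target drawn around
    ``base + comp_shift``, so the mean latent link of the sampled
    membership moves by (approximately) the requested shift while the
    feature marginals stay realistic.
    """
    k = 8 if comp_shift != 0.0 else 1
    cand = pd.DataFrame({
        "gender": rng.choice(_GENDERS, k * n, p=(0.48, 0.48, 0.04)),
        "age": np.clip(np.rint(rng.normal(40.0, 12.0, k * n)), 18, 75).astype(int),
        "education_level": np.clip(np.rint(rng.normal(3.0, 1.1, k * n)), 1, 5).astype(int),
        "occupation": rng.choice(_OCCUPATIONS, k * n),
        "income_band": np.clip(np.rint(rng.normal(3.0, 1.2, k * n)), 1, 5).astype(int),
        "location": rng.choice(_LOCATIONS, k * n),
    })
    if k > 1:
        links = profile_anxiety_link(cand).reshape(k, n)
        target = rng.normal(_LINK_BASE + comp_shift, 0.10, n)
        pick = np.abs(links - target).argmin(axis=0) * n + np.arange(n)
        cand = cand.iloc[pick].reset_index(drop=True)
    cand.insert(0, "user_id", [f"{prefix}u{i:05d}" for i in range(n)])
    cand["is_influencer"] = rng.random(n) < influencer_fraction
    cand["is_verified"] = rng.random(n) < verified_fraction
    cand["is_organizational"] = np.zeros(n, dtype=bool)
    return cand


def profile_anxiety_link(profiles: pd.DataFrame) -> np.ndarray:
    """The documented linear link from profile features to the latent
    anxiety scale in [0,1] (kept inside (0,1) by construction)."""
    g = profiles["gender"].map(_GENDER_EFF).to_numpy(dtype=float)
    o = profiles["occupation"].map(_OCC_EFF).to_numpy(dtype=float)
    loc = profiles["location"].map(_LOC_EFF).to_numpy(dtype=float)
    return (_LINK_BASE
            + _AGE_COEF * (profiles["age"].to_numpy(dtype=float) - 40.0)
            + _EDU_COEF * (profiles["education_level"].to_numpy(dtype=float) - 3.0)
            + _INC_COEF * (profiles["income_band"].to_numpy(dtype=float) - 3.0)
            + g + o + loc)


#: Constant offset between the latent anxiety link and the SAS index scale;
#: keeps the noise-free index inside [25, 100] for every feasible profile, so
#: the noiseless score is an exact (unclipped) linear function of the profile.
SAS_LINK_OFFSET = 0.13


def generate_sas_training(n: int = 360, seed: int = 0, noise_sd: float = 4.0
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Volunteer profile table plus linked SAS records.

    SAS index = 25 + 75 * (link(profile) + offset) + Normal(0, noise_sd),
    clipped to [25, 100]; with ``noise_sd=0`` the score is an exact linear
    function of the encoded profile features (the offset keeps it off the
    scale bounds).
    """
    if n < 30:
        raise ValueError("need n >= 30 volunteers (cross-validation undefined below)")
    rng = np.random.default_rng([seed, 1])
    profiles = _draw_profiles(rng, n, prefix="sas")
    score = SAS_MIN + (SAS_MAX - SAS_MIN) * (profile_anxiety_link(profiles)
                                             + SAS_LINK_OFFSET)
    if noise_sd > 0:
        score = score + rng.normal(0.0, noise_sd, n)
    score = np.clip(score, SAS_MIN, SAS_MAX)
    records = pd.DataFrame({
        "user_id": profiles["user_id"],
        "score": score,
        "category": [band_sas_score(s) for s in score],
    })
    return profiles, records


def _follower_edges(rng: np.random.Generator, profiles: pd.DataFrame,
                    mean_out_degree: float, influencer_fitness: float) -> pd.DataFrame:
    """Directed follower edges from a fitness-weighted attachment rule.

    Each account follows ~Poisson(mean_out_degree) others, picked with
    probability proportional to a heavy-tailed fitness that is multiplied
    for influencer accounts, which therefore accumulate systematically
    higher in-degree (the "volume of non-reciprocal follows").
    """
    n = len(profiles)
    fitness = 1.0 + rng.pareto(2.5, n)
    fitness[profiles["is_influencer"].to_numpy()] *= influencer_fitness
    p = fitness / fitness.sum()
    d_out = rng.poisson(mean_out_degree, n)
    src = np.repeat(np.arange(n), d_out)
    dst = rng.choice(n, size=src.size, p=p)
    keep = src != dst
    pairs = np.unique(np.stack([src[keep], dst[keep]], axis=1), axis=0)
    ids = profiles["user_id"].to_numpy()
    return pd.DataFrame({"src": ids[pairs[:, 0]], "dst": ids[pairs[:, 1]]})


def _assemble_text(tokens: list[str], two_sentences: bool, marker1: str | None,
                   marker2: str | None, hashtag: str) -> str:
    if two_sentences and len(tokens) >= 4:
        cut = len(tokens) // 2
        s1, s2 = tokens[:cut], tokens[cut:]
    else:
        s1, s2 = tokens, []
    if marker1 and len(s1) > 1:
        s1 = [s1[0], marker1, *s1[1:]]
    if s2 and marker2 and len(s2) > 1:
        s2 = [s2[0], marker2, *s2[1:]]
    text = " ".join(s1) + "."
    if s2:
        text += " " + " ".join(s2) + "."
    return text + f" #{hashtag}#"


def _community_messages(rng: np.random.Generator, config: SyntheticConfig,
                        cid: str, field_name: str, hashtag: str,
                        profiles: pd.DataFrame, latent: np.ndarray,
                        mood: np.ndarray, dk_c: float) -> pd.DataFrame:
    n = len(profiles)
    days = config.n_days
    topic_pool = TOPIC_WORDS[field_name]
    anchors = ANXIETY_ANCHORS
    stop_pool = sorted(STOPWORDS - set(CLAUSE_MARKERS))[:40]
    markers = CLAUSE_MARKERS

    # one day-0 onboarding post per member, then a fixed community message
    # budget spread multinomially over members (per-member counts are
    # approximately Poisson, but the total is pinned to the budget)
    total_extra = max(int(round((config.messages_per_user_mean - 1.0) * n
                                + rng.normal(0.0, 0.6 * np.sqrt(n)))), 0)
    n_extra = rng.multinomial(total_extra, np.full(n, 1.0 / n))
    m_total = n + total_extra
    uidx = np.concatenate([np.arange(n), np.repeat(np.arange(n), n_extra)])
    later_days = np.arange(1, days)
    if config.arrival_decay_days > 0:
        w = np.exp(-later_days / config.arrival_decay_days)
    else:
        w = np.ones(later_days.size)
    day = np.concatenate([np.zeros(n, dtype=int),
                          rng.choice(later_days, size=m_total - n, p=w / w.sum())])
    kind_code = np.concatenate([np.zeros(n, dtype=int),
                                rng.choice(3, size=m_total - n, p=(0.45, 0.35, 0.2))])
    order = np.argsort(day, kind="stable")
    uidx, day, kind_code = uidx[order], day[order], kind_code[order]

    # token counts, wired to the latent/mood (anchors) and dk (the rest)
    p_anchor = 1.0 / (1.0 + np.exp(-config.anchor_slope
                                   * (latent[uidx] + config.mood_gain * mood[day]
                                      - 0.5)))
    has_anchor = rng.random(m_total) < p_anchor
    n_topic = rng.poisson(0.5 + 1.8 * dk_c, m_total)
    n_neut = 1 + rng.poisson(1.5, m_total)
    n_rare = rng.poisson(1.5 * (1.0 - dk_c), m_total)
    n_pron = rng.poisson(0.2 + 0.8 * (1.0 - dk_c), m_total)
    n_stop = rng.integers(1, 3, m_total)

    anchor_ix = rng.integers(0, len(anchors), m_total)
    topic_ix = rng.integers(0, len(topic_pool), int(n_topic.sum()))
    u = rng.random(int(n_neut.sum()))
    neut_ix = np.minimum((len(NEUTRAL_WORDS) * u ** (1.0 + 1.5 * dk_c)).astype(int),
                         len(NEUTRAL_WORDS) - 1)
    rare_ix = rng.integers(0, len(RARE_WORDS), int(n_rare.sum()))
    pron_ix = rng.integers(0, len(PERSONAL_PRONOUNS), int(n_pron.sum()))
    stop_ix = rng.integers(0, len(stop_pool), int(n_stop.sum()))
    rot = rng.integers(0, 7, m_total)
    two_sent = rng.random(m_total) < 0.35
    p_marker = np.clip(0.65 - 0.45 * dk_c, 0.05, 0.95)
    use_marker = rng.random((m_total, 2)) < p_marker
    marker_ix = rng.integers(0, len(markers), (m_total, 2))

    to, no, ro, po, so = (np.concatenate([[0], np.cumsum(c)]) for c in
                          (n_topic, n_neut, n_rare, n_pron, n_stop))
    texts = []
    for i in range(m_total):
        toks = [topic_pool[j] for j in topic_ix[to[i]:to[i + 1]]]
        toks += [NEUTRAL_WORDS[j] for j in neut_ix[no[i]:no[i + 1]]]
        if has_anchor[i]:
            toks.append(anchors[anchor_ix[i]])
        toks += [RARE_WORDS[j] for j in rare_ix[ro[i]:ro[i + 1]]]
        toks += [PERSONAL_PRONOUNS[j] for j in pron_ix[po[i]:po[i + 1]]]
        toks += [stop_pool[j] for j in stop_ix[so[i]:so[i + 1]]]
        k = rot[i] % len(toks)
        toks = toks[k:] + toks[:k]
        texts.append(_assemble_text(
            toks, two_sent[i],
            markers[marker_ix[i, 0]] if use_marker[i, 0] else None,
            markers[marker_ix[i, 1]] if use_marker[i, 1] else None,
            hashtag))

    ids = [f"{cid}m{i:06d}" for i in range(m_total)]
    kinds = np.array(["post", "repost", "comment"])[kind_code]
    parent = _assign_parents(rng, day, kind_code, ids,
                             profiles["is_verified"].to_numpy()[uidx], dk_c)
    user_ids = profiles["user_id"].to_numpy()[uidx]
    return pd.DataFrame({
        "id": ids, "user": user_ids, "day": day, "text": texts,
        "hashtags": [hashtag] * m_total, "kind": kinds, "parent": parent,
        "community": cid,
    })


def _assign_parents(rng, day, kind_code, ids, author_verified, dk_c):
    """Parents for reposts/comments among strictly earlier messages.

    Reposts preferentially trace to posts by verified authors with
    probability increasing in the community knowledge level; comments reply
    to any earlier message.
    """
    m = len(ids)
    parent = np.full(m, None, dtype=object)
    q_verified = float(np.clip(0.15 + 0.6 * dk_c, 0.0, 0.9))
    posts, verified_posts, all_prev = [], [], []
    i = 0
    while i < m:
        j = i
        while j < m and day[j] == day[i]:
            j += 1
        for t in range(i, j):
            if kind_code[t] == 1 and all_prev:          # repost
                if rng.random() < 0.2:
                    parent[t] = ids[all_prev[rng.integers(len(all_prev))]]
                elif verified_posts and rng.random() < q_verified:
                    parent[t] = ids[verified_posts[rng.integers(len(verified_posts))]]
                elif posts:
                    parent[t] = ids[posts[rng.integers(len(posts))]]
            elif kind_code[t] == 2 and all_prev:        # comment
                parent[t] = ids[all_prev[rng.integers(len(all_prev))]]
        for t in range(i, j):
            all_prev.append(t)
            if kind_code[t] == 0:
                posts.append(t)
                if author_verified[t]:
                    verified_posts.append(t)
        i = j
    # reposts/comments on day 0 with no earlier message become plain posts
    return parent


def generate_community(config: SyntheticConfig, community_index: int
                       ) -> tuple[TopicCommunity, LatentTruth]:
    """One seeded community with its latent ground truth."""
    rng = np.random.default_rng([config.seed, 1000 + community_index])
    cid = f"c{community_index:04d}"
    field_name = TOPIC_FIELDS[community_index % len(TOPIC_FIELDS)]
    hashtag = f"{field_name}{community_index}"
    familiarity = int(rng.random() < 0.5)
    proximity = int(rng.random() < 0.5)
    dk_c = float(rng.uniform(0.0, 1.0))
    f_c = float(rng.uniform(0.0, min(1.0, 2.0 * config.influencer_fraction)))
    b_c = float(rng.normal(0.0, config.community_sd))
    sigma_c = float(max(config.noise_sd + config.effect_influencer_sd * f_c, 0.002))
    lo, hi = config.size_range
    # right-skewed sizes, like real hashtag communities: many small, few large
    n = int(lo + np.floor((hi - lo + 1) * rng.beta(2.5, 4.5)))

    # proximity acts through who joins (member composition); the knowledge
    # effect splits half composition / half topical expression
    comp_shift = (config.effect_proximity * proximity
                  + 0.5 * config.effect_dk * (dk_c - 0.5))
    direct_shift = 0.5 * config.effect_dk * (dk_c - 0.5) + b_c
    profiles = _draw_profiles(rng, n, prefix=cid, comp_shift=comp_shift,
                              influencer_fraction=f_c,
                              verified_fraction=config.verified_fraction)
    latent = np.clip(profile_anxiety_link(profiles) + direct_shift
                     + rng.normal(0.0, config.member_sd, n), 0.0, 1.0)
    mood = np.concatenate([[0.0], np.cumsum(rng.normal(0.0, sigma_c,
                                                       config.n_days - 1))])
    edges = _follower_edges(rng, profiles, config.mean_out_degree,
                            config.influencer_fitness)
    messages = _community_messages(rng, config, cid, field_name, hashtag,
                                   profiles, latent, mood, dk_c)
    # reposts/comments that found no earlier parent fall back to plain posts
    orphan = messages["parent"].isna() & (messages["kind"] != "post")
    messages.loc[orphan, "kind"] = "post"

    true_mean = float(latent.mean())
    truth = LatentTruth(
        community_id=cid,
        user_latent=pd.Series(latent, index=profiles["user_id"], name="latent"),
        true_mean=true_mean,
        true_rating=rate_community(true_mean),
        dk_wired=dk_c,
        influencer_fraction_wired=f_c,
        mood_sigma=sigma_c,
        base_shift=b_c,
    )
    community = TopicCommunity(cid, field_name, familiarity, proximity,
                               profiles, messages, edges)
    return community, truth


def generate_corpus(config: SyntheticConfig) -> Corpus:
    """Full corpus: communities, ground truth, questionnaire pool, word
    vectors and frequency lexicon, plus a manifest echoing the config."""
    communities, truths = zip(*(generate_community(config, i)
                                for i in range(config.n_communities)))
    profiles = pd.concat([c.profiles.assign(community=c.community_id)
                          for c in communities], ignore_index=True)
    messages = pd.concat([c.messages for c in communities], ignore_index=True)
    edges = pd.concat([c.edges.assign(community=c.community_id)
                       for c in communities], ignore_index=True)
    comm_df = pd.DataFrame({
        "id": [c.community_id for c in communities],
        "field": [c.field for c in communities],
        "familiarity": [c.familiarity for c in communities],
        "proximity": [c.proximity for c in communities],
    })
    truth_df = pd.DataFrame({
        "community_id": [t.community_id for t in truths],
        "true_mean": [t.true_mean for t in truths],
        "true_rating": [t.true_rating for t in truths],
        "dk_wired": [t.dk_wired for t in truths],
        "influencer_fraction_wired": [t.influencer_fraction_wired for t in truths],
        "mood_sigma": [t.mood_sigma for t in truths],
        "base_shift": [t.base_shift for t in truths],
    })
    user_truth = pd.concat(
        [t.user_latent.rename_axis("user_id").reset_index() for t in truths],
        ignore_index=True)
    sas_profiles, sas_records = generate_sas_training(360, seed=config.seed)
    manifest = {"config": _manifest_config(config), "format_version": 1}
    return Corpus(profiles, messages, edges, comm_df, truth_df, user_truth,
                  sas_profiles, sas_records,
                  build_embedding(config.embedding_dim, config.seed),
                  build_frequency_lexicon(), manifest)


def _manifest_config(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["size_range"] = list(d["size_range"])
    return d
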