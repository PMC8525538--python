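"""End-to-end analysis: corpus -> daily series -> features -> hypothesis report.

The daily evaluation uses cumulative snapshots: at day t a community
consists of the members, messages and relation edges active up to and
including t.  For each day the member scores are rebuilt (profile factor,
topical factor, Eq.-style mix), the cascade is run on the day's relation
matrix, and the collective score is normalized; fluctuation and trend
statistics then summarize the daily series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contagion import (MAX_ITERATION_DEPTH, CollectiveAnxietySeries,
                        ContagionParams, build_relation_matrix,
                        collective_anxiety, propagation_power)
from .knowledge import (DKWeights, extract_readability_features, readability_raw,
                        scale_readability)
from .lexicon import AnchorLexicon
from .scoring import ProfileScorer, ScorerSettings, normalize_sas, train_profile_scorer
from .stats import (graph_diameter, graph_metrics, hypothesis_battery,
                    influencer_ratio, precision_recall, rate_community)
from .text import extract_keywords

__all__ = ["AnalysisResult", "train_default_scorer", "user_profile_scores",
           "message_scores", "community_daily_series", "run_full_analysis"]


@dataclass
class AnalysisResult:
    features: pd.DataFrame
    series: dict[str, CollectiveAnxietySeries]
    series_table: pd.DataFrame        # community_id, day, A, n_members_active
    dk_table: pd.DataFrame            # community_id, day, DK (cumulative)
    report: dict
    validation: object | None = None  # ValidationCounts when truth is present
    scored_messages: pd.DataFrame | None = None


def train_default_scorer(corpus, seed: int = 0) -> ProfileScorer:
    """Train the profile scorer on the corpus's questionnaire pool."""
    return train_profile_scorer(corpus.sas_profiles, corpus.sas_records,
                                ScorerSettings(seed=seed))


def user_profile_scores(corpus, scorer: ProfileScorer) -> pd.Series:
    """Profile-factor score p in [0,1] per (personal) corpus user."""
    prof = corpus.profiles[~corpus.profiles["is_organizational"].astype(bool)]
    p = normalize_sas(scorer.predict(prof))
    return pd.Series(p, index=prof["user_id"].to_numpy(), name="p")


def message_scores(corpus, lexicon: AnchorLexicon | None = None,
                   dk_weights: DKWeights = DKWeights(),
                   keywords_k: int = 5, difficult_top_n: int = 5000) -> pd.DataFrame:
    """Per-message anchor similarity and declarative-knowledge components.

    One pass over the messages computes, for every message: the topical
    anchor similarity feeding the member factor m, the topic similarity,
    the raw readability index and the origin credibility.  Readability is
    z-scored (and negated) within the corpus before entering DK.
    """
    lexicon = lexicon or corpus.anchor_lexicon
    emb = corpus.embedding
    anchor_sim_of = emb.max_similarity_table(lexicon.words, lexicon.weights)
    field_of = dict(zip(corpus.communities["id"], corpus.communities["field"]))
    label_vec = {f: emb.vector(f) for f in set(field_of.values()) if f in emb}
    label_norm = {f: np.linalg.norm(v) for f, v in label_vec.items()}

    msgs = corpus.messages
    origin = _resolve_origins(msgs)
    verified = dict(zip(corpus.profiles["user_id"],
                        corpus.profiles["is_verified"].astype(bool)))
    author = dict(zip(msgs["id"], msgs["user"]))

    anchor_sims = np.zeros(len(msgs))
    topic_sims = np.zeros(len(msgs))
    read_raw = np.zeros(len(msgs))
    cred = np.zeros(len(msgs), dtype=int)
    texts = msgs["text"].to_numpy()
    comms = msgs["community"].to_numpy()
    origins = [origin.get(mid) for mid in msgs["id"]]
    # per-token projections onto the (unit) label vector and squared norms,
    # so the mean-keyword-vector cosine reduces to cached dot products
    label_unit = {f: v / label_norm[f] for f, v in label_vec.items()}
    for i, text in enumerate(texts):
        kws = extract_keywords(text, k=keywords_k)
        best = 0.0
        vecs = []
        for kw in kws:
            s = anchor_sim_of.get(kw)
            if s is not None and s > best:
                best = s
            if kw in emb:
                vecs.append(emb.vector(kw))
        anchor_sims[i] = best
        fld = field_of.get(comms[i])
        if vecs and fld in label_unit:
            mean = vecs[0] if len(vecs) == 1 else np.add.reduce(vecs) / len(vecs)
            nrm = math.sqrt(float(mean @ mean))
            if nrm > 0:
                c = float(mean @ label_unit[fld]) / nrm
                topic_sims[i] = 0.0 if c < 0.0 else (1.0 if c > 1.0 else c)
        feats = extract_readability_features(text, corpus.word_freq,
                                             top_n=difficult_top_n)
        read_raw[i] = readability_raw(feats)
        org = origins[i]
        if org is not None:
            cred[i] = int(verified.get(author.get(org), False))

    read_scaled = scale_readability(read_raw)
    dk = (dk_weights.a * cred + dk_weights.b * topic_sims
          + dk_weights.c * read_scaled)
    return msgs.assign(anchor_sim=anchor_sims, topic_sim=topic_sims,
                       readability_raw=read_raw, readability=read_scaled,
                       credibility=cred, dk=dk)


def _resolve_origins(msgs: pd.DataFrame) -> dict:
    """Root of each message's repost/comment chain, with path compression.

    Parents outside the dataset resolve to None (origin unknown); cycles
    are an error.
    """
    parent = dict(zip(msgs["id"], msgs["parent"]))
    root: dict = {}
    for mid in parent:
        if mid in root:
            continue
        chain = []
        cur = mid
        while True:
            if cur in root:
                res = root[cur]
                break
            chain.append(cur)
            nxt = parent.get(cur)
            if nxt is None or (isinstance(nxt, float) and np.isnan(nxt)):
                res = cur
                break
            if nxt not in parent:
                res = None
                break
            if nxt in chain:
                raise ValueError(f"cycle in repost chain at {nxt!r}")
            cur = nxt
        for c in chain:
            root[c] = res
    return root


def _corpus_norm_params(corpus, params: ContagionParams) -> ContagionParams:
    sizes = corpus.profiles.groupby("community").size()
    if params.norm_mode == "saturating" and params.tau is None:
        params = params.with_norm(tau=float(sizes.mean()) * params.ub)
    if params.norm_mode == "global_max" and params.n_max is None:
        params = params.with_norm(n_max=int(sizes.max()))
    return params


def _community_run(cid, profiles, scored_msgs, follow_edges, p_series,
                   params: ContagionParams, n_days: int):
    """Daily series plus the community feature row, from scored messages."""
    personal = ~profiles["is_organizational"].astype(bool)
    profiles = profiles[personal]
    members = profiles["user_id"].to_numpy()
    member_ix = {u: i for i, u in enumerate(members)}
    n = len(members)
    msgs = scored_msgs[scored_msgs["user"].isin(member_ix)]

    author = dict(zip(msgs["id"], msgs["user"]))
    inter_pairs, inter_days = [], []
    for mid, user, par, day in zip(msgs["id"], msgs["user"], msgs["parent"],
                                   msgs["day"]):
        if par is None or (isinstance(par, float) and np.isnan(par)):
            continue
        pu = author.get(par)
        if pu is not None and pu != user:
            inter_pairs.append((user, pu))
            inter_days.append(int(day))
    follow_pairs = [(s, d) for s, d in zip(follow_edges["src"], follow_edges["dst"])
                    if s in member_ix and d in member_ix]

    R = build_relation_matrix(members, follow_pairs)
    R_final = R.copy()
    for (u, v) in inter_pairs:
        i, j = member_ix[u], member_ix[v]
        R_final[i, j] = R_final[j, i] = 1.0
    diameter = graph_diameter(members, follow_pairs + inter_pairs)
    k = params.k if params.k is not None else min(diameter, MAX_ITERATION_DEPTH)

    p = p_series.reindex(members).to_numpy(dtype=float)
    uidx = msgs["user"].map(member_ix).to_numpy()
    day_arr = msgs["day"].to_numpy()
    sim_arr = msgs["anchor_sim"].to_numpy(dtype=float)
    dk_arr = msgs["dk"].to_numpy(dtype=float)

    sim_sum = np.zeros(n)
    cnt = np.zeros(n)
    days_out, a_out, n_act_out, dk_out = [], [], [], []
    dk_cum = 0.0
    inter_by_day: dict[int, list] = {}
    for (u, v), d in zip(inter_pairs, inter_days):
        inter_by_day.setdefault(d, []).append((member_ix[u], member_ix[v]))

    for t in range(n_days):
        sel = day_arr == t
        if sel.any():
            np.add.at(sim_sum, uidx[sel], sim_arr[sel])
            np.add.at(cnt, uidx[sel], 1.0)
            dk_cum += float(dk_arr[sel].sum())
        for i, j in inter_by_day.get(t, ()):
            if i != j:
                R[i, j] = R[j, i] = 1.0
        active = cnt > 0
        if not active.any():
            continue  # series starts at the first active day
        m = np.divide(sim_sum, cnt, out=np.zeros(n), where=active)
        a = (params.lam * p + (1.0 - params.lam) * m) * active
        for _ in range(k):
            delta = propagation_power(a, params) * active
            a = a + (R @ delta) * active
            if params.clip_to_ub:
                a = np.clip(a, 0.0, params.ub)
        days_out.append(t)
        a_out.append(collective_anxiety(a, params))
        n_act_out.append(int(active.sum()))
        dk_out.append(dk_cum)

    series = CollectiveAnxietySeries(
        community_id=cid, days=np.array(days_out), a=np.array(a_out),
        n_active=np.array(n_act_out)).assess()

    n_posts = int((msgs["kind"] != "comment").sum())
    n_reposts = int((msgs["kind"] == "repost").sum())
    n_comments = int((msgs["kind"] == "comment").sum())
    gm = graph_metrics(members, follow_pairs + inter_pairs, inter_pairs,
                       n_reposts, n_comments, n_days, diameter=diameter)
    avg_a = float(np.mean(series.a)) if series.a.size else float("nan")
    feature_row = {
        "community_id": cid,
        "n_members": n,
        "n_posts": n_posts,
        "n_comments": n_comments,
        "influencer_ratio": influencer_ratio(profiles),
        "dk_level": float(dk_arr.mean()) if dk_arr.size else 0.0,
        "interaction_frequency": gm.interaction_frequency,
        "edge_density": gm.edge_density,
        "diameter": gm.diameter,
        "avg_collective_anxiety": avg_a,
        "anxiety_sd": series.fluctuation if series.fluctuation is not None else float("nan"),
        "trend_slope": series.trend_slope,
        "polarized": series.polarized,
        "rating": rate_community(avg_a) if np.isfinite(avg_a) else None,
        "cascade_depth": k,
    }
    dk_rows = [{"community_id": cid, "day": d, "DK": v}
               for d, v in zip(days_out, dk_out)]
    return series, feature_row, dk_rows


def community_daily_series(corpus, community_id, scorer: ProfileScorer,
                           params: ContagionParams | None = None,
                           lexicon: AnchorLexicon | None = None,
                           dk_weights: DKWeights = DKWeights()) -> CollectiveAnxietySeries:
    """Daily collective-anxiety series for a single community."""
    params = _corpus_norm_params(corpus, params or ContagionParams())
    sub = _corpus_subset(corpus, community_id)
    scored = message_scores(sub, lexicon=lexicon, dk_weights=dk_weights)
    p = user_profile_scores(sub, scorer)
    n_days = int(corpus.manifest.get("config", {}).get("n_days",
                                                       corpus.messages["day"].max() + 1))
    series, _, _ = _community_run(community_id, sub.profiles, scored, sub.edges,
                                  p, params, n_days)
    return series


def _corpus_subset(corpus, community_id):
    from copy import copy

    sub = copy(corpus)
    sub.profiles = corpus.profiles[corpus.profiles["community"] == community_id]
    sub.messages = corpus.messages[corpus.messages["community"] == community_id]
    sub.edges = corpus.edges[corpus.edges["community"] == community_id]
    sub.communities = corpus.communities[corpus.communities["id"] == community_id]
    return sub


def run_full_analysis(corpus, scorer: ProfileScorer | None = None,
                      params: ContagionParams | None = None,
                      lexicon: AnchorLexicon | None = None,
                      dk_weights: DKWeights = DKWeights(),
                      seed: int = 0, holm: bool = False,
                      keep_scored_messages: bool = False) -> AnalysisResult:
    """Score -> cascade -> knowledge -> hypothesis battery over a corpus."""
    params = _corpus_norm_params(corpus, params or ContagionParams())
    scorer = scorer or train_default_scorer(corpus, seed=seed)
    p_all = user_profile_scores(corpus, scorer)
    scored = message_scores(corpus, lexicon=lexicon, dk_weights=dk_weights)
    n_days = int(corpus.manifest.get("config", {}).get("n_days",
                                                       corpus.messages["day"].max() + 1))

    prof_by_comm = dict(tuple(corpus.profiles.groupby("community", sort=True)))
    msgs_by_comm = dict(tuple(scored.groupby("community", sort=True)))
    edges_by_comm = dict(tuple(corpus.edges.groupby("community", sort=True)))
    empty_edges = corpus.edges.iloc[0:0]

    series_map, feat_rows, dk_rows_all, series_rows = {}, [], [], []
    for cid in corpus.communities["id"]:
        series, row, dk_rows = _community_run(
            cid, prof_by_comm[cid], msgs_by_comm.get(cid, scored.iloc[0:0]),
            edges_by_comm.get(cid, empty_edges), p_all, params, n_days)
        series_map[cid] = series
        feat_rows.append(row)
        dk_rows_all.extend(dk_rows)
        for d, a, na in zip(series.days, series.a, series.n_active):
            series_rows.append({"community_id": cid, "day": int(d),
                                "A": float(a), "n_members_active": int(na)})

    features = pd.DataFrame(feat_rows).merge(
        corpus.communities.rename(columns={"id": "community_id"}),
        on="community_id")
    report = hypothesis_battery(features, holm=holm)

    validation = None
    if corpus.truth is not None and len(corpus.truth):
        merged = features.merge(corpus.truth, on="community_id")
        validation = precision_recall(merged["rating"], merged["true_rating"])
        report["validation"] = {"tp": validation.tp, "fp": validation.fp,
                                "fn": validation.fn,
                                "precision": validation.precision,
                                "recall": validation.recall}
    return AnalysisResult(features=features, series=series_map,
                          series_table=pd.DataFrame(series_rows),
                          dk_table=pd.DataFrame(dk_rows_all),
                          report=report, validation=validation,
                          scored_messages=scored if keep_scored_messages else None)
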