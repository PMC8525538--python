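"""Corpus readers/writers and run configuration.

On-disk corpus layout (all plain text, UTF-8)::

    profiles.csv        user profiles incl. account flags and community
    messages.jsonl      one message per line: id, user, day, text,
                        hashtags, kind, parent, community
    edges.tsv           directed follower edges: src, dst, community
    communities.csv     id, field, familiarity, proximity
    truth.csv           community-level ground truth (synthetic corpora)
    user_truth.csv      per-user latent anxiety (synthetic corpora)
    sas_profiles.csv /  questionnaire pool for training the profile
    sas_records.csv       scorer
    wordvec.txt         text word2vec vectors
    wordfreq.tsv        token<TAB>count frequency lexicon
    manifest.json       config echo, seed, format version
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .embeddings import read_word2vec, write_word2vec
from .lexicon import read_frequency_lexicon, write_frequency_lexicon
from .synth import Corpus

__all__ = ["write_corpus", "read_corpus", "load_run_config"]

_REQUIRED_FILES = ("profiles.csv", "messages.jsonl", "edges.tsv",
                   "communities.csv", "wordvec.txt", "wordfreq.tsv",
                   "manifest.json")

_PROFILE_COLS = ("user_id", "gender", "age", "education_level", "occupation",
                 "income_band", "location", "is_influencer", "is_verified",
                 "is_organizational", "community")


def write_corpus(corpus: Corpus, directory) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    corpus.profiles.to_csv(d / "profiles.csv", index=False)
    corpus.sas_profiles.to_csv(d / "sas_profiles.csv", index=False)
    corpus.sas_records.to_csv(d / "sas_records.csv", index=False)
    corpus.communities.to_csv(d / "communities.csv", index=False)
    if corpus.truth is not None:
        corpus.truth.to_csv(d / "truth.csv", index=False)
    if corpus.user_truth is not None:
        corpus.user_truth.to_csv(d / "user_truth.csv", index=False)
    corpus.edges.to_csv(d / "edges.tsv", sep="\t", index=False)
    with open(d / "messages.jsonl", "w", encoding="utf-8") as fh:
        for rec in corpus.messages.itertuples(index=False):
            row = {"id": rec.id, "user": rec.user, "day": int(rec.day),
                   "text": rec.text, "hashtags": _as_taglist(rec.hashtags),
                   "kind": rec.kind, "parent": _none_if_nan(rec.parent),
                   "community": rec.community}
            fh.write(json.dumps(row, sort_keys=True) + "\n")
    write_word2vec(corpus.embedding, d / "wordvec.txt")
    write_frequency_lexicon(corpus.word_freq, d / "wordfreq.tsv")
    with open(d / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(corpus.manifest, fh, sort_keys=True, indent=2)
        fh.write("\n")
    return d


def _as_taglist(tags):
    if isinstance(tags, str):
        return [tags]
    return list(tags)


def _none_if_nan(v):
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return v


def read_corpus(directory) -> Corpus:
    """Read and cross-validate a corpus directory.

    Reference errors (messages or edges pointing at unknown users or
    communities) are collected and reported together.
    """
    d = Path(directory)
    missing = [f for f in _REQUIRED_FILES if not (d / f).exists()]
    if missing:
        raise FileNotFoundError(f"corpus at {d} is missing file(s): {missing}")

    profiles = pd.read_csv(d / "profiles.csv", float_precision="round_trip")
    for col in ("is_influencer", "is_verified", "is_organizational"):
        profiles[col] = profiles[col].astype(bool)
    communities = pd.read_csv(d / "communities.csv", float_precision="round_trip")
    edges = pd.read_csv(d / "edges.tsv", sep="\t", float_precision="round_trip")
    rows = []
    with open(d / "messages.jsonl", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"messages.jsonl:{lineno}: malformed JSON ({exc})")
            rec["hashtags"] = ";".join(rec.get("hashtags") or [])
            rows.append(rec)
    messages = pd.DataFrame(rows, columns=["id", "user", "day", "text",
                                           "hashtags", "kind", "parent",
                                           "community"])
    truth = pd.read_csv(d / "truth.csv", float_precision="round_trip") if (d / "truth.csv").exists() else None
    user_truth = (pd.read_csv(d / "user_truth.csv", float_precision="round_trip")
                  if (d / "user_truth.csv").exists() else None)
    sas_profiles = (pd.read_csv(d / "sas_profiles.csv", float_precision="round_trip")
                    if (d / "sas_profiles.csv").exists() else None)
    sas_records = (pd.read_csv(d / "sas_records.csv", float_precision="round_trip")
                   if (d / "sas_records.csv").exists() else None)
    with open(d / "manifest.json", encoding="utf-8") as fh:
        manifest = json.load(fh)

    errors = []
    users = set(profiles["user_id"])
    comm_ids = set(communities["id"])
    unknown_msg_users = sorted(set(messages["user"]) - users)
    if unknown_msg_users:
        errors.append(f"messages reference unknown users: {unknown_msg_users[:10]}")
    unknown_edge = sorted((set(edges["src"]) | set(edges["dst"])) - users)
    if unknown_edge:
        errors.append(f"edges reference unknown users: {unknown_edge[:10]}")
    unknown_comm = sorted(set(messages["community"]) - comm_ids)
    if unknown_comm:
        errors.append(f"messages reference unknown communities: {unknown_comm[:10]}")
    if "community" in profiles.columns:
        unknown_pc = sorted(set(profiles["community"].dropna()) - comm_ids)
        if unknown_pc:
            errors.append(f"profiles reference unknown communities: {unknown_pc[:10]}")
    if errors:
        raise ValueError("corpus cross-reference errors:\n  " + "\n  ".join(errors))

    return Corpus(profiles=profiles, messages=messages, edges=edges,
                  communities=communities, truth=truth, user_truth=user_truth,
                  sas_profiles=sas_profiles, sas_records=sas_records,
                  embedding=read_word2vec(d / "wordvec.txt"),
                  word_freq=read_frequency_lexicon(d / "wordfreq.tsv"),
                  manifest=manifest)


def load_run_config(path) -> dict[str, dict]:
    """Flat ``section.key = value`` configuration file.

    Values are parsed as Python literals when possible, otherwise kept as
    strings.  Returns {section: {key: value}}.
    """
    import ast

    out: dict[str, dict] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line or "." not in line.split("=", 1)[0]:
                raise ValueError(f"{path}:{lineno}: expected 'section.key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            section, name = key.split(".", 1)
            try:
                parsed = ast.literal_eval(value)
            except (ValueError, SyntaxError):
                parsed = value
            out.setdefault(section, {})[name] = parsed
    return out
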