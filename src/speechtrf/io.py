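"""Serialisation: HDF5 cohort containers, Praat TextGrids, TSV tables.

The cohort container layout is::

    /config                  YAML string of the simulation config
    /language                JSON string (inventories, grammars, lexicon, ...)
    /montage/names, pos2d
    /stimulus/trial<t>       (n_times, 43) master feature matrix
    /transcripts/trial<t>    JSON string
    /subjects/<id>/eeg       (n_trials, n_times, n_channels)
                             attrs: group, level

Ground-truth kernels are simulation-time objects and are not serialised.
"""

from __future__ import annotations

import json
import re

import h5py
import numpy as np
import pandas as pd
import yaml

from .features import GROUP_DIMS, FeatureMatrix
from .languages import (EmbeddingTable, LexiconEntry, Phone,
                        StimulusTranscript, ToyLanguagePair, Word)
from .montage import Montage
from .phonotactics import Constraint, PhonotacticGrammar
from .synthetic import Cohort, CohortConfig, SubjectRecord
from .trf import TRFResults, PredictionScore


# ---------------------------------------------------------------------------
# JSON codecs for the domain objects

def transcript_to_dict(tr: StimulusTranscript) -> dict:
    return {
        "duration": tr.duration,
        "phones": [[p.symbol, p.start, p.end] for p in tr.phones],
        "words": [[w.text, *w.phone_span, int(w.content), w.start, w.end]
                  for w in tr.words],
        "sentences": [list(s) for s in tr.sentence_spans],
    }


def transcript_from_dict(d: dict) -> StimulusTranscript:
    return StimulusTranscript(
        phones=[Phone(s, a, b) for s, a, b in d["phones"]],
        words=[Word(t, (i0, i1), bool(c), a, b)
               for t, i0, i1, c, a, b in d["words"]],
        sentence_spans=[tuple(s) for s in d["sentences"]],
        duration=d["duration"])


def _grammar_to_dict(g: PhonotacticGrammar) -> dict:
    return {"inventory": g.inventory,
            "constraints": [[list(c.pattern), c.weight] for c in g.constraints]}


def _grammar_from_dict(d: dict) -> PhonotacticGrammar:
    return PhonotacticGrammar(
        [Constraint(tuple(p), w) for p, w in d["constraints"]],
        list(d["inventory"]))


def language_to_dict(lang: ToyLanguagePair) -> dict:
    return {
        "inventory_l1": lang.inventory_l1, "inventory_l2": lang.inventory_l2,
        "shared": lang.shared, "unique_l2": lang.unique_l2,
        "grammar_l1": _grammar_to_dict(lang.grammar_l1),
        "grammar_l2": _grammar_to_dict(lang.grammar_l2),
        "feature_table": {p: [int(v) for v in lang.feature_table.loc[p]]
                          for p in lang.feature_table.index},
        "feature_names": list(lang.feature_table.columns),
        "lexicon": [[e.text, list(e.phones), int(e.content)]
                    for e in lang.lexicon],
        "embeddings": {w: list(map(float, v))
                       for w, v in (lang.embeddings.vectors.items()
                                    if lang.embeddings else [])},
        "embedding_dim": lang.embeddings.dim if lang.embeddings else 0,
    }


def language_from_dict(d: dict) -> ToyLanguagePair:
    table = pd.DataFrame.from_dict(d["feature_table"], orient="index",
                                   columns=d["feature_names"])
    emb = None
    if d.get("embedding_dim"):
        emb = EmbeddingTable({w: np.array(v) for w, v in d["embeddings"].items()},
                             dim=d["embedding_dim"])
    return ToyLanguagePair(
        d["inventory_l1"], d["inventory_l2"], d["shared"], d["unique_l2"],
        _grammar_from_dict(d["grammar_l1"]), _grammar_from_dict(d["grammar_l2"]),
        table, [LexiconEntry(t, tuple(p), bool(c)) for t, p, c in d["lexicon"]],
        emb)


# ---------------------------------------------------------------------------
# cohort container

def _master_groups() -> dict[str, slice]:
    groups, start = {}, 0
    for name, width in GROUP_DIMS.items():
        groups[name] = slice(start, start + width)
        start += width
    return groups


def save_cohort(cohort: Cohort, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("config", data=yaml.safe_dump(vars(cohort.config)))
        f.create_dataset("language",
                         data=json.dumps(language_to_dict(cohort.lang)))
        m = f.create_group("montage")
        m.create_dataset("names", data=[n.encode() for n in cohort.montage.names])
        m.create_dataset("pos2d", data=cohort.montage.pos2d)
        st = f.create_group("stimulus")
        trg = f.create_group("transcripts")
        for t, (fm, tr) in enumerate(zip(cohort.stimulus, cohort.transcripts)):
            d = st.create_dataset(f"trial{t}", data=fm.values)
            d.attrs["fs"] = fm.fs
            trg.create_dataset(f"trial{t}",
                               data=json.dumps(transcript_to_dict(tr)))
        sub = f.create_group("subjects")
        for s in cohort.subjects:
            g = sub.create_group(s.subject_id)
            g.create_dataset("eeg", data=np.stack(s.eeg))
            g.attrs["group"] = s.group
            g.attrs["level"] = -1 if s.level is None else s.level
            g.attrs["fs"] = s.fs


def load_cohort(path: str) -> Cohort:
    with h5py.File(path, "r") as f:
        cfg = CohortConfig(**yaml.safe_load(f["config"][()].decode()))
        lang = language_from_dict(json.loads(f["language"][()].decode()))
        montage = Montage([n.decode() for n in f["montage/names"][()]],
                          f["montage/pos2d"][()])
        groups = _master_groups()
        stimulus, transcripts = [], []
        for t in range(len(f["stimulus"])):
            d = f[f"stimulus/trial{t}"]
            stimulus.append(FeatureMatrix(d[()], float(d.attrs["fs"]), groups))
            transcripts.append(transcript_from_dict(
                json.loads(f[f"transcripts/trial{t}"][()].decode())))
        subjects = []
        for sid in f["subjects"]:
            g = f[f"subjects/{sid}"]
            level = int(g.attrs["level"])
            subjects.append(SubjectRecord(
                subject_id=sid, group=str(g.attrs["group"]),
                level=None if level < 0 else level,
                eeg=list(g["eeg"][()]), fs=float(g.attrs["fs"])))
    return Cohort(subjects, stimulus, transcripts, lang, montage, cfg)


# ---------------------------------------------------------------------------
# TRF model container

def save_trf(res: TRFResults, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("weights", data=res.weights)
        f.create_dataset("bias", data=res.bias)
        f.create_dataset("lags", data=res.lags)
        f.attrs["lambda"] = res.lambda_
        f.attrs["fs"] = res.fs
        f.attrs["lag_window_ms"] = res.lag_window_ms
        f.attrs["groups"] = json.dumps({g: [s.start, s.stop]
                                        for g, s in res.groups.items()})
        if res.channel_names:
            f.attrs["channels"] = json.dumps(res.channel_names)
        if res.score is not None:
            f.create_dataset("score_per_trial", data=res.score.per_trial)


def load_trf(path: str) -> TRFResults:
    with h5py.File(path, "r") as f:
        groups = {g: slice(a, b) for g, (a, b)
                  in json.loads(f.attrs["groups"]).items()}
        res = TRFResults(
            weights=f["weights"][()], bias=f["bias"][()],
            lambda_=float(f.attrs["lambda"]), lags=f["lags"][()],
            lag_window_ms=tuple(f.attrs["lag_window_ms"]),
            fs=float(f.attrs["fs"]), groups=groups,
            channel_names=(json.loads(f.attrs["channels"])
                           if "channels" in f.attrs else None))
        if "score_per_trial" in f:
            res.score = PredictionScore(f["score_per_trial"][()])
    return res


# ---------------------------------------------------------------------------
# Praat TextGrid (long format, interval tiers "phones" and "words")

def write_textgrid(tr: StimulusTranscript, path: str) -> None:
    def tier(name: str, items: list[tuple[float, float, str]]) -> str:
        lines = [f'        class = "IntervalTier"',
                 f'        name = "{name}"',
                 f"        xmin = 0",
                 f"        xmax = {tr.duration}",
                 f"        intervals: size = {len(items)}"]
        for i, (a, b, text) in enumerate(items, 1):
            lines += [f"        intervals [{i}]:",
                      f"            xmin = {a}",
                      f"            xmax = {b}",
                      f'            text = "{text}"']
        return "\n".join(lines)

    phones = [(p.start, p.end, p.symbol) for p in tr.phones]
    words = [(w.start, w.end, w.text) for w in tr.words]
    content = ('File type = "ooTextFile"\nObject class = "TextGrid"\n\n'
               f"xmin = 0\nxmax = {tr.duration}\ntiers? <exists>\nsize = 2\n"
               "item []:\n"
               "    item [1]:\n" + tier("phones", phones) + "\n"
               "    item [2]:\n" + tier("words", words) + "\n")
    with open(path, "w") as fh:
        fh.write(content)


def read_textgrid(path: str) -> dict[str, list[tuple[float, float, str]]]:
    """Parse a long-format TextGrid into {tier name: [(xmin, xmax, text)]}."""
    with open(path) as fh:
        text = fh.read()
    tiers: dict[str, list[tuple[float, float, str]]] = {}
    blocks = re.split(r"item \[\d+\]:", text)[1:]
    for block in blocks:
        name_m = re.search(r'name = "([^"]*)"', block)
        if name_m is None:
            continue
        items = []
        for m in re.finditer(
                r"intervals \[\d+\]:\s*xmin = ([\d.eE+-]+)\s*"
                r"xmax = ([\d.eE+-]+)\s*text = \"([^\"]*)\"", block):
            items.append((float(m.group(1)), float(m.group(2)), m.group(3)))
        tiers[name_m.group(1)] = items
    return tiers


# ---------------------------------------------------------------------------
# TSV tables

def write_embeddings_tsv(emb: EmbeddingTable, path: str) -> None:
    df = emb.to_frame()
    df.columns = [f"v{i + 1}" for i in range(df.shape[1])]
    df.to_csv(path, sep="\t", index_label="word")


def read_embeddings_tsv(path: str) -> EmbeddingTable:
    df = pd.read_csv(path, sep="\t", index_col="word")
    return EmbeddingTable.from_frame(df)


def write_grammar_tsv(g: PhonotacticGrammar, path: str) -> None:
    rows = [{"constraint": i + 1, "weight": c.weight,
             "pattern": " ".join(c.pattern)}
            for i, c in enumerate(g.constraints)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_grammar_tsv(path: str, inventory: list[str]) -> PhonotacticGrammar:
    df = pd.read_csv(path, sep="\t")
    cons = [Constraint(tuple(str(r.pattern).split()), float(r.weight))
            for r in df.itertuples()]
    return PhonotacticGrammar(cons, inventory)
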