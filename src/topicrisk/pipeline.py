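"""End-to-end pipeline: synth -> preprocess -> dictionary -> embed ->
classify -> cluster -> keywords, driven by one declarative config.

Stage order mirrors the mining workflow: a topic dictionary is expanded
from seed phrases using a plain Skip-gram model, the topic-enhanced
embedding is then trained with that dictionary's supervision, the
classifier flags risk-factor comments, and the flagged comments are
clustered and summarized by keywords.  Every stage writes its artifacts
into the run directory and records their SHA-256 hashes in a manifest;
a rerun with the same config resumes from the last completed stage, and a
manifest written by a different config is refused as stale.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import classifier as clf
from . import clusterrev, embedding, keywords, preprocess, synthetic, topicdict

__all__ = ["PipelineConfig", "run_pipeline", "validate_config"]

log = logging.getLogger("topicrisk.pipeline")

STAGES = ["synth", "preprocess", "dictionary", "embed",
          "classify", "cluster", "keywords"]


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_run"
    rng_seed: int = 0
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES})
    # synth
    generator: synthetic.GeneratorConfig = field(
        default_factory=synthetic.GeneratorConfig)
    seed_words_per_topic: int = 5
    # external inputs used when the synth stage is off
    corpus_path: str | None = None
    seeds_path: str | None = None
    stopwords_path: str | None = None
    user_dictionary_path: str | None = None
    # preprocess
    min_tokens: int = 3
    min_count: int = 1
    # dictionary expansion
    expansion: topicdict.ExpansionConfig = field(
        default_factory=topicdict.ExpansionConfig)
    base_epochs: int = 3  # plain Skip-gram used only for expansion
    # embedding
    training: embedding.TrainingConfig = field(
        default_factory=lambda: embedding.TrainingConfig(dimension=32))
    # classifier
    classifier: clf.ClassifierConfig = field(
        default_factory=lambda: clf.ClassifierConfig(
            max_len=16, filters_per_size=16, epochs=5))
    # clustering / keywords
    theta: float = 0.5
    top_keywords: int = 10
    keyword_config: keywords.KeywordConfig = field(
        default_factory=keywords.KeywordConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise KeyError(f"unknown config key: {key}")
            current = getattr(cfg, key)
            if dataclasses.is_dataclass(current) and isinstance(value, dict):
                value = dataclasses.replace(current, **value)
            elif key == "stages" and isinstance(value, dict):
                value = {**cfg.stages, **value}
            setattr(cfg, key, value)
        return cfg

    def fingerprint(self) -> str:
        # stage on/off flags and the output location do not change artifact
        # content, so they are excluded: enabling a later stage must not
        # invalidate completed ones
        skip = {"stages", "out_dir"}

        def enc(o):
            if dataclasses.is_dataclass(o):
                return {f.name: enc(getattr(o, f.name))
                        for f in dataclasses.fields(o)
                        if not f.name.endswith("pattern")
                        and not (o is self and f.name in skip)}
            if isinstance(o, dict):
                return {str(k): enc(v) for k, v in sorted(o.items())}
            if isinstance(o, (list, tuple, set, frozenset)):
                return [enc(v) for v in o]
            return repr(o)
        return hashlib.sha256(
            json.dumps(enc(self), sort_keys=True).encode()).hexdigest()


def validate_config(cfg: PipelineConfig) -> list[str]:
    """Static diagnostics; an empty list means the config looks runnable."""
    diags = []
    if not (0 < cfg.theta < 1):
        diags.append(f"theta must be in (0, 1), got {cfg.theta}")
    if cfg.training.lam < 0:
        diags.append(f"lambda must be non-negative, got {cfg.training.lam}")
    if cfg.min_tokens < 1:
        diags.append(f"min_tokens must be >= 1, got {cfg.min_tokens}")
    if not cfg.stages.get("synth", False):
        if not cfg.corpus_path:
            diags.append("synth stage disabled but no corpus_path given")
        elif not Path(cfg.corpus_path).exists():
            diags.append(f"corpus_path does not exist: {cfg.corpus_path}")
        if not cfg.seeds_path and cfg.stages.get("dictionary", False):
            diags.append("dictionary stage needs seeds_path when synth is off")
    for needed, stage in [("cluster", "keywords"), ("embed", "classify"),
                          ("embed", "cluster")]:
        if cfg.stages.get(stage, False) and not cfg.stages.get(needed, False):
            out = Path(cfg.out_dir)
            marker = {"cluster": "assignments.tsv",
                      "embed": "vectors.w2v"}[needed]
            if not (out / marker).exists():
                diags.append(
                    f"stage '{stage}' needs '{needed}' outputs "
                    f"({marker}) but stage '{needed}' is disabled")
    return diags


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _Run:
    """Stage bookkeeping: artifact hashing, manifest, resume."""

    def __init__(self, cfg: PipelineConfig, resume: bool):
        self.cfg = cfg
        self.out = Path(cfg.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        self.manifest = {"config_hash": cfg.fingerprint(),
                         "rng_seed": cfg.rng_seed, "stages": {}}
        if self.manifest_path.exists():
            with open(self.manifest_path, encoding="utf-8") as fh:
                previous = json.load(fh)
            if resume:
                if previous.get("config_hash") != self.manifest["config_hash"]:
                    raise RuntimeError(
                        "stale manifest: config changed since the recorded "
                        "run; refusing to resume (delete the run directory "
                        "or use a fresh out_dir)")
                self.manifest["stages"] = previous.get("stages", {})

    def done(self, stage: str) -> bool:
        rec = self.manifest["stages"].get(stage)
        if not rec:
            return False
        for name, digest in rec["artifacts"].items():
            p = self.out / name
            if not p.exists() or _sha256(p) != digest:
                return False
        return True

    def record(self, stage: str, artifacts: list[Path], t0: float) -> None:
        # wall-clock goes to the log, not the manifest, so reruns with the
        # same seeds produce byte-identical manifests
        log.info("stage %s took %.2fs", stage, time.time() - t0)
        self.manifest["stages"][stage] = {
            "artifacts": {p.name: _sha256(p) for p in artifacts},
        }
        with open(self.manifest_path, "w", encoding="utf-8") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)


def run_pipeline(cfg: PipelineConfig, resume: bool = True) -> dict:
    """Execute the enabled stages in order; returns the manifest dict."""
    diags = validate_config(cfg)
    if diags:
        raise ValueError("invalid pipeline config: " + "; ".join(diags))
    run = _Run(cfg, resume)
    out = run.out
    for stage in STAGES:
        if not cfg.stages.get(stage, False):
            log.info("stage %s: disabled", stage)
            continue
        if resume and run.done(stage):
            log.info("stage %s: already complete, skipping", stage)
            continue
        t0 = time.time()
        try:
            artifacts = _STAGE_FUNCS[stage](cfg, out)
        except Exception as exc:
            raise RuntimeError(f"pipeline halted at stage '{stage}': {exc}"
                               ) from exc
        run.record(stage, artifacts, t0)
        log.info("stage %s: %d artifacts in %.2fs", stage, len(artifacts),
                 time.time() - t0)
    return run.manifest


# --------------------------------------------------------------------------
# stages

def _stage_synth(cfg: PipelineConfig, out: Path) -> list[Path]:
    gen = dataclasses.replace(cfg.generator, rng_seed=cfg.rng_seed)
    comments, truth, true_dict = synthetic.generate_corpus(gen)
    phrases = synthetic.generate_seed_phrases(gen, cfg.seed_words_per_topic)
    raw = out / "raw_comments.tsv"
    with open(raw, "w", encoding="utf-8") as fh:
        fh.write("comment_id\ttext\tlabel\n")
        for c in comments:
            fh.write(f"{c.comment_id}\t{c.raw_text}\t{c.label}\n")
    gt = out / "ground_truth.json"
    gt.write_text(json.dumps(truth, indent=1, sort_keys=True))
    seeds = out / "seed_phrases.json"
    seeds.write_text(json.dumps(phrases, indent=1))
    td = out / "true_dictionary.json"
    true_dict.save_json(td)
    return [raw, gt, seeds, td]


def _load_corpus(cfg: PipelineConfig, out: Path) -> list[preprocess.Comment]:
    path = cfg.corpus_path if cfg.corpus_path else out / "raw_comments.tsv"
    return preprocess.read_comments(path)


def _stage_preprocess(cfg: PipelineConfig, out: Path) -> list[Path]:
    comments = _load_corpus(cfg, out)
    stop = (frozenset(preprocess.read_wordlist(cfg.stopwords_path))
            if cfg.stopwords_path else frozenset())
    udict = (tuple(preprocess.read_wordlist(cfg.user_dictionary_path))
             if cfg.user_dictionary_path else ())
    ccfg = preprocess.CleaningConfig(stopwords=stop, user_dictionary=udict,
                                     min_tokens=cfg.min_tokens)
    kept, dropped = preprocess.run_preprocess(comments, ccfg)
    vocab = preprocess.build_vocab(kept, min_count=cfg.min_count)
    tok = out / "tokenized.jsonl"
    preprocess.write_comments_jsonl(kept, tok)
    drop = out / "dropped.jsonl"
    preprocess.write_comments_jsonl(dropped, drop)
    voc = out / "vocab.tsv"
    vocab.save_tsv(voc)
    return [tok, drop, voc]


def _stage_dictionary(cfg: PipelineConfig, out: Path) -> list[Path]:
    kept = preprocess.read_comments_jsonl(out / "tokenized.jsonl")
    vocab = preprocess.Vocabulary.load_tsv(out / "vocab.tsv")
    if cfg.seeds_path:
        # one risk-factor topic seeded from a flat word list
        phrase_groups = [[preprocess.read_wordlist(cfg.seeds_path)]]
    else:
        # per-topic phrase lists written by the synth stage
        phrase_groups = [[grp] for grp
                         in json.loads((out / "seed_phrases.json").read_text())]
    base_cfg = dataclasses.replace(cfg.training, lam=0.0,
                                   epochs=cfg.base_epochs,
                                   rng_seed=cfg.rng_seed)
    base = embedding.train(kept, None, base_cfg, vocab=vocab)
    tdict = topicdict.TopicDictionary()
    for t, phrases in enumerate(phrase_groups):
        seeds = topicdict.seeds_from_phrases(phrases)
        expanded = topicdict.expand_topic(seeds, base, cfg.expansion)
        topicdict.assign_weights(expanded, f"topic{t}", risk=True,
                                 topic_dict=tdict)
    path = out / "topic_dictionary.json"
    tdict.save_json(path)
    return [path]


def _stage_embed(cfg: PipelineConfig, out: Path) -> list[Path]:
    kept = preprocess.read_comments_jsonl(out / "tokenized.jsonl")
    vocab = preprocess.Vocabulary.load_tsv(out / "vocab.tsv")
    tdict = topicdict.TopicDictionary.load_json(out / "topic_dictionary.json")
    tcfg = dataclasses.replace(cfg.training, rng_seed=cfg.rng_seed)
    model = embedding.train(kept, tdict, tcfg, vocab=vocab)
    vec = out / "vectors.w2v"
    embedding.save_word2vec(model, vec)
    curve = out / "loss_curve.csv"
    with open(curve, "w", encoding="utf-8") as fh:
        fh.write("epoch,l_cont,l_topic,l_s\n")
        for row in model.loss_curve:
            fh.write(f"{row['epoch']},{row['l_cont']!r},"
                     f"{row['l_topic']!r},{row['l_s']!r}\n")
    return [vec, curve]


def _load_model(cfg: PipelineConfig, out: Path) -> embedding.EmbeddingModel:
    vocab = preprocess.Vocabulary.load_tsv(out / "vocab.tsv")
    words, rows = embedding.load_word2vec(out / "vectors.w2v")
    model = embedding.EmbeddingModel.initialize(vocab, cfg.training)
    order = [vocab.index[w] for w in words]
    model.w_in[order] = rows
    return model


def _stage_classify(cfg: PipelineConfig, out: Path) -> list[Path]:
    kept = preprocess.read_comments_jsonl(out / "tokenized.jsonl")
    model = _load_model(cfg, out)
    labeled = clf.LabeledDataset([c for c in kept if c.is_labeled()])
    ccfg = dataclasses.replace(cfg.classifier, rng_seed=cfg.rng_seed)
    train_ds, test_ds = labeled.split(0.1, seed=cfg.rng_seed)
    params = clf.train_classifier(train_ds, model, ccfg)
    report = clf.evaluate(params, test_ds, model, ccfg)
    metrics = out / "classifier_metrics.json"
    metrics.write_text(json.dumps(report.to_json(), indent=1, sort_keys=True))
    flagged = clf.predict_corpus(params, kept, model, ccfg)
    flg = out / "flagged.tsv"
    with open(flg, "w", encoding="utf-8") as fh:
        fh.write("comment_id\tprobability\n")
        for c, p in flagged:
            fh.write(f"{c.comment_id}\t{p!r}\n")
    return [metrics, flg]


def _stage_cluster(cfg: PipelineConfig, out: Path) -> list[Path]:
    kept = {c.comment_id: c
            for c in preprocess.read_comments_jsonl(out / "tokenized.jsonl")}
    model = _load_model(cfg, out)
    flagged_ids = []
    with open(out / "flagged.tsv", encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            flagged_ids.append(line.split("\t")[0])
    docs = [clusterrev.doc_vector(kept[cid], model) for cid in flagged_ids]
    cs = clusterrev.single_pass(docs, cfg.theta)
    cs = clusterrev.review_pass(cs)
    assign = out / "assignments.tsv"
    cs.save_assignments_tsv(assign)
    rep = out / "cluster_report.json"
    report = clusterrev.review_report(cs, list(kept.values()))
    rep.write_text(json.dumps(report, indent=1, sort_keys=True))
    return [assign, rep]


def _stage_keywords(cfg: PipelineConfig, out: Path) -> list[Path]:
    kept = {c.comment_id: c
            for c in preprocess.read_comments_jsonl(out / "tokenized.jsonl")}
    by_cat: dict[str, list[str]] = {}
    with open(out / "assignments.tsv", encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            cid, cat = line.rstrip("\n").split("\t")
            if cat != "-1":
                by_cat.setdefault(cat, []).extend(kept[cid].tokens)
    kw = out / "keywords.tsv"
    artifacts = [kw]
    with open(kw, "w", encoding="utf-8") as fh:
        fh.write("category\trank\tword\tweight\n")
        for cat in sorted(by_cat, key=int):
            tops = keywords.top_keywords(by_cat[cat], cfg.top_keywords,
                                         cfg.keyword_config)
            for rank, (w, s) in enumerate(tops, 1):
                fh.write(f"{cat}\t{rank}\t{w}\t{s:.6f}\n")
            cloud = out / f"wordcloud_cat{cat}.tsv"
            keywords.wordcloud_export(dict(tops), cloud)
            artifacts.append(cloud)
    return artifacts


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "preprocess": _stage_preprocess,
    "dictionary": _stage_dictionary,
    "embed": _stage_embed,
    "classify": _stage_classify,
    "cluster": _stage_cluster,
    "keywords": _stage_keywords,
}
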