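"""End-to-end pipeline: simulate -> filter -> stats -> adjudicate ->
featurize -> train -> crossval -> classify -> retrieve.

One global seed drives every stochastic stage (fixed per-stage offsets), so a
repeat run with the same configuration produces byte-identical artifacts.
Every run writes a ``run_manifest.json`` stamped with the configuration hash
and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import analytics, dbn, evaluation, retrieval, synthetic
from .features import FeatureSpec, build_vocabulary, featurize_all
from .ingest import FilterConfig, TweetStore, apply_filter, read_jsonl, write_jsonl
from .labels import adjudicate, fleiss_kappa
from .synthetic import ConfigError, GeneratorConfig

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "PipelineError"]

# per-stage seed offsets (all derived seeds stay below 2**31)
_SEED_RATERS = 1
_SEED_FOLDS = 2
_SEED_UNLABELED = 3
_SEED_PRETRAIN = 4
_SEED_FINETUNE = 5
_MOD = 2**31 - 1


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage_seed(seed: int, offset: int) -> int:
    return (int(seed) * 1000003 + offset) % _MOD


def _config_hash(config: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode("utf-8")
    ).hexdigest()[:16]


def _write_stats(store: TweetStore, out: Path, cfg: Mapping) -> dict:
    series = analytics.daily_counts(store)
    series.rename_axis("date").reset_index().to_csv(out / "daily_counts.csv", index=False)
    spikes = analytics.zscore_spikes(series, threshold=cfg.get("z_threshold", 2.0))
    spikes.table.to_csv(out / "spikes.csv", index=False)
    tags = analytics.hashtag_stats(store)
    tags.table.to_csv(out / "hashtags.csv", index=False)
    users = analytics.user_concentration(store, min_tweets=cfg.get("min_tweets", 10))
    pd.DataFrame([asdict(users)]).to_csv(out / "users.csv", index=False)
    rts = analytics.retweet_summary(store, viral_cutoff=cfg.get("viral_cutoff", 500))
    pd.DataFrame(
        [
            {
                "total": rts.total,
                "n_retweets": rts.n_retweets,
                "retweet_fraction": rts.retweet_fraction,
                "n_viral": rts.n_viral,
                "viral_cutoff": rts.viral_cutoff,
            }
        ]
    ).to_csv(out / "retweets.csv", index=False)
    return {
        "mean_tweets_per_day": spikes.mean,
        "sd_tweets_per_day": spikes.sd,
        "n_spike_days": len(spikes.flagged),
        "spike_days": [str(d) for d in spikes.flagged],
        "retweet_fraction": rts.retweet_fraction,
        "n_distinct_hashtags": tags.n_distinct,
        "hashtag_usages": tags.total_usages,
        "heavy_user_share": users.heavy_user_share,
    }


def run_pipeline(config: Mapping, out_dir: str | Path) -> dict:
    """Execute the configured stages; returns a summary dict.

    ``config`` keys (all optional unless noted): ``seed`` (int, default 0),
    ``stages`` (list; default all), ``generator`` (GeneratorConfig overrides),
    ``corpus`` (path to an existing JSONL corpus instead of simulating),
    ``filter`` ({include_terms, exclude_patterns}), ``stats``, ``raters``
    ({n_raters, agreement, n_items}), ``training`` ({hidden_sizes, pretrain,
    finetune, n_unlabeled}), ``evaluation`` ({k}), ``retrieval``
    ({category, thresholds}).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    all_stages = [
        "simulate", "filter", "stats", "adjudicate", "featurize",
        "train", "crossval", "classify", "retrieve",
    ]
    stages = list(config.get("stages", all_stages))
    unknown = set(stages) - set(all_stages)
    if unknown:
        raise ConfigError(f"stages: unknown stage(s) {sorted(unknown)}")
    summary: dict = {"seed": seed, "config_hash": _config_hash(dict(config))}

    # --- simulate / load -------------------------------------------------
    stage = "simulate"
    try:
        gen_cfg = GeneratorConfig(**{**config.get("generator", {}), "seed": seed})
        scheme = gen_cfg.scheme()
        if "corpus" in config:
            store, skipped = read_jsonl(config["corpus"])
            truth: dict[str, str] = {}
            if "truth_labels" in config:
                df = pd.read_csv(config["truth_labels"], dtype=str)
                truth = dict(zip(df["tweet_id"], df["category"]))
            summary["n_skipped_lines"] = skipped
        else:
            store, truth = synthetic.generate_corpus(gen_cfg)
            if "simulate" in stages:
                write_jsonl(store, out / "corpus.jsonl")
                pd.DataFrame(
                    sorted(truth.items()), columns=["tweet_id", "category"]
                ).to_csv(out / "truth_labels.csv", index=False)
        summary["n_tweets"] = len(store)
    except (ConfigError, OSError) as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    # --- filter -----------------------------------------------------------
    if "filter" in stages and "filter" in config:
        stage = "filter"
        try:
            fcfg = FilterConfig(
                include_terms=tuple(config["filter"]["include_terms"]),
                exclude_patterns=tuple(config["filter"].get("exclude_patterns", ())),
            )
            store = apply_filter(store, fcfg)
            truth = {k: v for k, v in truth.items() if k in store}
            write_jsonl(store, out / "filtered.jsonl")
            summary["n_tweets_after_filter"] = len(store)
        except (KeyError, ValueError) as exc:
            raise PipelineError(f"stage {stage}: {exc}") from exc

    # --- stats ------------------------------------------------------------
    if "stats" in stages:
        stage = "stats"
        try:
            summary["stats"] = _write_stats(store, out, config.get("stats", {}))
        except ValueError as exc:
            raise PipelineError(f"stage {stage}: {exc}") from exc

    labeled = None
    # --- adjudicate -------------------------------------------------------
    if "adjudicate" in stages:
        stage = "adjudicate"
        try:
            rcfg = config.get("raters", {})
            n_items = int(rcfg.get("n_items", 1000))
            rng = np.random.default_rng(_stage_seed(seed, _SEED_RATERS))
            ids = sorted(truth)
            if len(ids) > n_items:
                ids = sorted(rng.choice(ids, size=n_items, replace=False))
            sample = {i: truth[i] for i in ids}
            if not sample:
                raise ValueError("no labeled items available for adjudication")
            table = synthetic.generate_rater_table(
                sample,
                n_raters=int(rcfg.get("n_raters", 3)),
                agreement=float(rcfg.get("agreement", gen_cfg.rater_agreement)),
                seed=_stage_seed(seed, _SEED_RATERS),
                scheme=scheme,
            )
            table.to_csv(out / "votes.csv")
            kappa = fleiss_kappa(table, scheme)
            labeled = adjudicate(table, min_agree=int(rcfg.get("min_agree", 2)))
            pd.DataFrame(
                sorted(labeled.labels.items()), columns=["tweet_id", "category"]
            ).to_csv(out / "labels.csv", index=False)
            pd.DataFrame({"tweet_id": sorted(labeled.dropped)}).to_csv(
                out / "dropped.csv", index=False
            )
            summary["fleiss_kappa"] = kappa
            summary["n_labeled"] = len(labeled.labels)
            summary["n_dropped"] = len(labeled.dropped)
        except ValueError as exc:
            raise PipelineError(f"stage {stage}: {exc}") from exc

    spec = None
    X_labeled = y_labeled = labeled_ids = None
    # --- featurize --------------------------------------------------------
    need_features = {"featurize", "train", "crossval", "classify", "retrieve"} & set(stages)
    if need_features:
        stage = "featurize"
        try:
            if labeled is None:
                raise ValueError("featurize requires the adjudicate stage")
            fcfg = config.get("features", {})
            texts_by_class = {
                c: [store[i].text for i, cat in labeled.labels.items() if cat == c]
                for c in scheme.names
            }
            vocab = build_vocabulary(
                texts_by_class,
                [t.text for t in store],
                per_class_top=int(fcfg.get("per_class_top", 50)),
                overall_top=int(fcfg.get("overall_top", 1000)),
            )
            spec = FeatureSpec(vocab)
            spec.to_json(out / "feature_spec.json")
            labeled_ids = sorted(labeled.labels)
            fm = featurize_all([store[i] for i in labeled_ids], spec)
            X_labeled = fm.X
            y_labeled = np.array(
                [scheme.index(labeled.labels[i]) for i in labeled_ids]
            )
            summary["n_features"] = spec.total_dim
        except ValueError as exc:
            raise PipelineError(f"stage {stage}: {exc}") from exc

    tcfg = config.get("training", {})
    hidden_sizes = tuple(tcfg.get("hidden_sizes", dbn.DEFAULT_HIDDEN_SIZES))
    pre_cfg = dbn.PretrainConfig(
        **{**tcfg.get("pretrain", {}), "seed": _stage_seed(seed, _SEED_PRETRAIN)}
    )
    fin_cfg = dbn.FinetuneConfig(
        **{**tcfg.get("finetune", {}), "seed": _stage_seed(seed, _SEED_FINETUNE)}
    )

    X_unlabeled = None
    if ({"train", "crossval"} & set(stages)) and spec is not None:
        n_unlab = int(tcfg.get("n_unlabeled", 10000))
        rng = np.random.default_rng(_stage_seed(seed, _SEED_UNLABELED))
        all_ids = [t.id for t in store]
        if len(all_ids) > n_unlab:
            chosen = sorted(rng.choice(all_ids, size=n_unlab, replace=False))
        else:
            chosen = all_ids
        X_unlabeled = featurize_all([store[i] for i in chosen], spec).X

    pretrained = None
    if X_unlabeled is not None and pre_cfg.epochs_per_layer > 0:
        sizes = (spec.total_dim, *hidden_sizes, len(scheme))
        pretrained = dbn.pretrain(X_unlabeled, sizes, pre_cfg, scheme.names)

    model = None
    # --- train ------------------------------------------------------------
    if "train" in stages:
        stage = "train"
        try:
            clf = dbn.DBNClassifier(
                scheme.names, hidden_sizes, pre_cfg, fin_cfg,
                initial_model=pretrained,
            )
            clf.fit(X_labeled, y_labeled)
            model = clf.model
            dbn.save_model(model, out / "model.bin")
        except ValueError as exc:
            raise PipelineError(f"stage {stage}: {exc}") from exc

    # --- crossval ---------------------------------------------------------
    if "crossval" in stages:
        stage = "crossval"
        try:
            k = int(config.get("evaluation", {}).get("k", 10))
            folds = evaluation.stratified_folds(
                y_labeled, k=k, seed=_stage_seed(seed, _SEED_FOLDS)
            )
            factory = lambda: dbn.DBNClassifier(  # noqa: E731
                scheme.names, hidden_sizes, pre_cfg, fin_cfg,
                initial_model=pretrained,
            )
            report = evaluation.cross_validate(
                X_labeled, [scheme.names[i] for i in y_labeled], factory, folds,
                scheme.names,
            )
            pd.DataFrame(
                {"fold": range(folds.k), "accuracy": report.fold_accuracy}
            ).to_csv(out / "cv_report.csv", index=False)
            report.per_class.to_csv(out / "per_class.csv", index=False)
            report.confusion.to_csv(out / "confusion.csv")
            summary["cv_accuracy"] = report.accuracy
            summary["cv_top2_accuracy"] = report.top2_accuracy
        except ValueError as exc:
            raise PipelineError(f"stage {stage}: {exc}") from exc

    scored = None
    # --- classify ---------------------------------------------------------
    if "classify" in stages:
        stage = "classify"
        try:
            if model is None:
                raise ValueError("classify requires the train stage")
            ids = [t.id for t in store]
            scores = dbn.predict_scores(model, featurize_all(store, spec).X)
            scored = retrieval.score_tweets(ids, scores, scheme)
            df = pd.DataFrame(scores, columns=list(scheme.names))
            df.insert(0, "tweet_id", ids)
            df["assigned_category"] = [s.category for s in scored]
            df.to_csv(out / "scores.csv", index=False)
            freqs = retrieval.category_frequencies([s.category for s in scored])
            pd.DataFrame(
                [(c, f.numerator, f.denominator, float(f)) for c, f in freqs.items()],
                columns=["category", "count", "total", "fraction"],
            ).to_csv(out / "category_frequencies.csv", index=False)
            summary["category_frequencies"] = {c: float(f) for c, f in freqs.items()}
        except ValueError as exc:
            raise PipelineError(f"stage {stage}: {exc}") from exc

    # --- retrieve ---------------------------------------------------------
    if "retrieve" in stages:
        stage = "retrieve"
        try:
            if scored is None:
                raise ValueError("retrieve requires the classify stage")
            rcfg = config.get("retrieval", {})
            category = rcfg.get("category", scheme.names[-1])
            thresholds = list(rcfg.get("thresholds", (0.3, 0.4, 0.5, 0.6, 0.7, 0.8)))
            counts = {}
            for thr in thresholds:
                hits = retrieval.retrieve(scored, category, thr, scheme)
                j = scheme.index(category)
                pd.DataFrame(
                    [(h.id, h.scores[j], store[h.id].text) for h in hits],
                    columns=["tweet_id", "score", "text"],
                ).to_csv(out / f"retrieved_{thr:.1f}.csv", index=False)
                counts[thr] = len(hits)
            summary["retrieval"] = {"category": category, "counts": counts}
        except ValueError as exc:
            raise PipelineError(f"stage {stage}: {exc}") from exc

    manifest = {
        "config_hash": summary["config_hash"],
        "seed": seed,
        "stages": stages,
        "summary": summary,
    }
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str), encoding="utf-8"
    )
    return summary
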