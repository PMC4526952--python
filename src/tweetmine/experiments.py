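"""Packaged end-to-end experiments on synthetic corpora.

These functions assemble the library stages into the study-level experiments
used for validation: corpus characterization at the default study conditions,
the simulated-rater agreement study, and the classifier parameter-recovery
experiment (disjoint per-category signature stems, semi-supervised training,
stratified cross-validation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import analytics, dbn, synthetic
from .evaluation import CVReport, cross_validate, stratified_folds
from .features import FeatureSpec, build_vocabulary, featurize_all
from .labels import adjudicate, fleiss_kappa

__all__ = [
    "characterize_default_corpus",
    "rater_agreement_study",
    "parameter_recovery_cv",
    "RecoveryResult",
]


def characterize_default_corpus(seed: int) -> dict:
    """Generate a corpus at the default study conditions and characterize it:
    daily volume, spike flagging, hashtags, retweets, user concentration."""
    cfg = synthetic.default_config(seed=seed)
    store, truth = synthetic.generate_corpus(cfg)
    series = analytics.daily_counts(store)
    spikes = analytics.zscore_spikes(series, threshold=2.0)
    injected = {
        series.index[day] for day, _ in cfg.spike_days
    }
    tags = analytics.hashtag_stats(store)
    rts = analytics.retweet_summary(store)
    users = analytics.user_concentration(store, min_tweets=10)
    return {
        "n_tweets": len(store),
        "n_days": len(series),
        "mean_tweets_per_day": spikes.mean,
        "sd_tweets_per_day": spikes.sd,
        "n_spike_days_flagged": len(spikes.flagged),
        "spike_days_match_injected": float(set(spikes.flagged) == injected),
        "retweet_fraction_pct": 100.0 * rts.retweet_fraction,
        "hashtag_usages_per_tweet": tags.total_usages / len(store),
        "heavy_user_share_pct": 100.0 * users.heavy_user_share,
    }


def rater_agreement_study(seed: int, n_items: int = 1000, n_raters: int = 3) -> dict:
    """Simulate independent raters at the default agreement level and
    adjudicate: Fleiss' kappa and the retained-labeled fraction."""
    cfg = synthetic.default_config(seed=seed)
    store, truth = synthetic.generate_corpus(cfg)
    rng = np.random.default_rng(seed + 1)
    ids = sorted(truth)
    if len(ids) > n_items:
        ids = sorted(rng.choice(ids, size=n_items, replace=False))
    sample = {i: truth[i] for i in ids}
    table = synthetic.generate_rater_table(
        sample, n_raters=n_raters, agreement=cfg.rater_agreement,
        seed=seed + 2, scheme=cfg.scheme(),
    )
    kappa = fleiss_kappa(table, cfg.scheme())
    labeled = adjudicate(table)
    return {
        "fleiss_kappa": kappa,
        "n_rated": len(sample),
        "labeled_fraction_pct": 100.0 * len(labeled.labels) / len(sample),
    }


@dataclass
class RecoveryResult:
    report: CVReport
    n_labeled: int
    n_unlabeled: int
    n_features: int


def parameter_recovery_cv(
    seed: int,
    n_labeled: int = 2000,
    n_unlabeled: int = 10000,
    k: int = 10,
    hidden_sizes: tuple[int, ...] = dbn.DEFAULT_HIDDEN_SIZES,
    pretrain_epochs: int = 10,
    finetune_epochs: int = 20,
) -> RecoveryResult:
    """Classifier parameter recovery on a disjoint-signature corpus.

    Generates a corpus large enough for ``n_labeled`` agreement-free labeled
    tweets (true generating categories) plus an ``n_unlabeled`` pretraining
    pool, builds the class-informed vocabulary, pretrains the RBM stack once
    on the unlabeled pool (pretraining never sees labels or fold membership)
    and fine-tunes per fold under stratified k-fold cross-validation.

    Fine-tuning runs ``finetune_epochs`` epochs (default 20) — a scaled-down
    pass budget suited to desk-scale corpora; the batch size, dropout and
    architecture are the library defaults.
    """
    n_needed = n_labeled + n_unlabeled
    cfg = synthetic.default_config(
        n_days=60,
        base_rate=float(np.ceil(n_needed * 1.1 / 60)),
        spike_days=(),
        seed=seed,
    )
    store, truth = synthetic.generate_corpus(cfg)
    if len(store) < n_needed:  # pragma: no cover - 10% headroom
        raise RuntimeError("generated corpus smaller than requested sample")
    scheme = cfg.scheme()
    rng = np.random.default_rng(seed + 10)
    ids = np.array(sorted(truth))
    rng.shuffle(ids)
    lab_ids = list(ids[:n_labeled])
    unlab_ids = list(ids[n_labeled : n_labeled + n_unlabeled])

    texts_by_class = {
        c: [store[i].text for i in lab_ids if truth[i] == c] for c in scheme.names
    }
    vocab = build_vocabulary(texts_by_class, [t.text for t in store])
    spec = FeatureSpec(vocab)
    X = featurize_all([store[i] for i in lab_ids], spec).X
    U = featurize_all([store[i] for i in unlab_ids], spec).X
    y = [truth[i] for i in lab_ids]

    pre_cfg = dbn.PretrainConfig(epochs_per_layer=pretrain_epochs, seed=seed + 20)
    fin_cfg = dbn.FinetuneConfig(epochs=finetune_epochs, seed=seed + 30)
    sizes = (spec.total_dim, *hidden_sizes, len(scheme))
    stack = dbn.pretrain(U.astype(float), sizes, pre_cfg, scheme.names)
    folds = stratified_folds(y, k=k, seed=seed + 40)
    factory = lambda: dbn.DBNClassifier(  # noqa: E731
        scheme.names, hidden_sizes, pre_cfg, fin_cfg, initial_model=stack
    )
    report = cross_validate(X, y, factory, folds, scheme.names)
    return RecoveryResult(report, n_labeled, len(unlab_ids), spec.total_dim)
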