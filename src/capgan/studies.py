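"""Reproducible desk-scale studies composing the package end to end.

These are the standard experiments the package ships with:

* :func:`phantom_progress_study` — does adversarial training move the
  generator toward the phantom distribution?  Measured with the
  KL-divergence quality metric against an untrained generator baseline.
* :func:`lesion_classifier_study` — the HOG+LBP+SVM evaluation classifier
  on the imbalanced two-class lesion set (75 malignant : 250 benign),
  trained on a stratified 80/20 split.
* :func:`pipeline_counts` — the bookkeeping of the data-preparation
  pipeline (augmentation expansion, stratified split sizes).

All sub-seeds fan out from one master seed.
"""

from __future__ import annotations

import numpy as np

from .gan import CapGAN, TrainConfig
from .networks import sample_latent, to_pixels
from .quality_eval import (FeatureParams, extract_features, train_eval_classifier,
                           evaluate_generated)
from .synthetic import (PhantomSpec, AugmentationConfig, generate_phantoms,
                        generate_lesion_dataset, roi_crop, split_dataset,
                        expand_with_originals, augment)

__all__ = [
    "make_unstructured_negatives", "train_realism_classifier",
    "phantom_progress_study", "lesion_classifier_study", "pipeline_counts",
]

#: feature extraction for 16x16 desk-scale images (finer HOG cells than the
#: 8-px default so 16x16 images yield more than one block)
DESK_FEATURES = FeatureParams(hog_cell=4)


def make_unstructured_negatives(images: np.ndarray, seed: int = 0) -> np.ndarray:
    """Structure-free counterparts of ``images`` for the realism classifier.

    One negative per input, drawn uniformly from three corruptions:
    pixel-shuffled (original histogram, no spatial structure), constant
    gray, and uniform noise.  Broad negative support keeps the classifier's
    probabilities informative on images far from the real manifold.
    """
    rng = np.random.default_rng(seed)
    neg = []
    for im in images:
        kind = rng.integers(3)
        if kind == 0:
            neg.append(rng.permutation(np.asarray(im).ravel()).reshape(im.shape))
        elif kind == 1:
            neg.append(np.full(im.shape, rng.integers(0, 256), dtype=np.uint8))
        else:
            neg.append(rng.integers(0, 256, size=im.shape).astype(np.uint8))
    return np.stack(neg).astype(np.uint8)


def train_realism_classifier(real_images: np.ndarray, seed: int = 0,
                             params: FeatureParams | None = None):
    """Two-class SVM separating real images from unstructured negatives."""
    params = params or DESK_FEATURES
    neg = make_unstructured_negatives(real_images, seed=seed)
    X = np.concatenate([real_images, neg])
    y = np.array([1] * len(real_images) + [0] * len(neg))
    return train_eval_classifier(extract_features(X, params), y, seed=seed)


def phantom_progress_study(seed: int = 0, n_phantoms: int = 1000, steps: int = 2000,
                           image_size: int = 16, n_eval: int = 500,
                           n_classifier: int = 250, n_bins: int = 10,
                           batch_size: int = 32) -> dict:
    """Train the GAN on phantoms and score it against an untrained baseline.

    Returns KL(real ‖ trained), KL(real ‖ untrained) and
    KL(real ‖ real held-out) under a realism classifier trained on phantoms
    disjoint from both the GAN training set and the evaluation set.
    """
    ss = np.random.SeedSequence(seed)
    s_fix, s_clf, s_train, s_sample = (int(c.generate_state(1, dtype=np.uint32)[0])
                                       for c in ss.spawn(4))
    spec = PhantomSpec(image_size=image_size, n_shells=3,
                       intensity_levels=(200, 130, 80), seed=s_fix)
    total = n_classifier + 2 * n_eval + n_phantoms
    imgs, _ = generate_phantoms(total, spec)
    clf_real = imgs[:n_classifier]
    held_out = imgs[n_classifier:n_classifier + n_eval]
    held_out2 = imgs[n_classifier + n_eval:n_classifier + 2 * n_eval]
    gan_set = imgs[n_classifier + 2 * n_eval:]

    params = DESK_FEATURES
    clf = train_realism_classifier(clf_real, seed=s_clf, params=params)

    model = CapGAN(gan_set, train_config=TrainConfig(batch_size=batch_size, seed=s_train))
    generator0, _, _, _ = model._build(s_train)
    z = sample_latent(np.random.default_rng(s_sample), n_eval,
                      model.gen_config.latent_dim, model.gen_config.prior)
    fake_untrained = to_pixels(generator0.forward(z))[..., 0]
    results = model.fit(steps=steps, seed=s_train)
    fake_trained = results.sample(n_eval, seed=s_sample)[..., 0]

    return {
        "kl_trained": evaluate_generated(held_out, fake_trained, clf, n_bins, params),
        "kl_untrained": evaluate_generated(held_out, fake_untrained, clf, n_bins, params),
        "kl_real_real": evaluate_generated(held_out, held_out2, clf, n_bins, params),
        "results": results,
        "n_train": len(gan_set),
        "steps": steps,
    }


def lesion_classifier_study(seed: int = 0, n_malignant: int = 75, n_benign: int = 250,
                            separability: float = 1.0, roi_side: int = 35) -> dict:
    """Fit the quality-metric classifier on ROI crops of the lesion set.

    Emulates the classification data flow: generate the imbalanced
    lesion set, crop each lesion to its ROI, split 80/20 stratified, train
    the HOG+LBP+SVM on the training crops and score the held-out crops.
    """
    records = generate_lesion_dataset(n_malignant, n_benign, seed=seed,
                                      separability=separability)
    train_recs, test_recs = split_dataset(records, train_fraction=0.8, seed=seed)
    params = FeatureParams()

    def _xy(recs):
        X = extract_features(np.stack([roi_crop(r, roi_side) for r in recs]), params)
        y = np.array([r.label == "malignant" for r in recs], dtype=int)
        return X, y

    X_tr, y_tr = _xy(train_recs)
    X_te, y_te = _xy(test_recs)
    clf = train_eval_classifier(X_tr, y_tr, seed=seed)
    from sklearn.metrics import roc_auc_score
    prob_te = clf.predict_proba(X_te)[:, 1]
    return {
        "holdout_accuracy": float(clf.score(X_te, y_te)),
        "holdout_auc": float(roc_auc_score(y_te, prob_te)),
        "n_train": len(train_recs), "n_test": len(test_recs),
        "n_train_malignant": int(y_tr.sum()), "n_test_malignant": int(y_te.sum()),
        "classifier": clf,
    }


def pipeline_counts(seed: int = 0, n_phantoms: int = 1400, phantom_fold: int = 10,
                    lesion_expand: int = 20, image_size: int = 64) -> dict:
    """Bookkeeping of the data-preparation pipeline at reference sizes.

    Phantoms are expanded ``phantom_fold``-fold by augmentation (no
    originals retained, 1400 -> 14,000); the lesion training split is
    expanded ``lesion_expand``-fold keeping originals (260 -> 5,460).
    """
    spec = PhantomSpec(image_size=image_size, seed=seed)
    phantoms, _ = generate_phantoms(n_phantoms, spec)
    aug_cfg = AugmentationConfig(seed=seed)
    rng = np.random.default_rng(seed)
    augmented = [a for img in phantoms for a in augment(img, aug_cfg, k=phantom_fold, rng=rng)]

    records = generate_lesion_dataset(seed=seed)
    train_recs, test_recs = split_dataset(records, train_fraction=0.8, seed=seed)
    train_patches = np.stack([roi_crop(r) for r in train_recs])
    expanded = expand_with_originals(train_patches, aug_cfg, k=lesion_expand, seed=seed)

    return {
        "n_phantoms": len(phantoms),
        "n_phantom_augmented": len(augmented),
        "n_lesions": len(records),
        "n_lesions_malignant": sum(r.label == "malignant" for r in records),
        "n_train": len(train_recs),
        "n_train_malignant": sum(r.label == "malignant" for r in train_recs),
        "n_test": len(test_recs),
        "n_test_malignant": sum(r.label == "malignant" for r in test_recs),
        "n_expanded_training": len(expanded),
    }
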