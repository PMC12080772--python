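"""Desk-scale end-to-end experiment: phantoms -> models -> counterfactual sweep.

This is the package's analogue of the full-scale pipeline: generate a
five-grade fundus phantom dataset, train an unconditional diffusion model
and plain + TRADES classifiers on the binary "referable" task (healthy and
mild versus moderate-or-worse), then sweep the distance-regularization
strength lambda_d over counterfactuals in both directions and measure flip
rates, image distances and oracle lesion-count changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifiers import (ConvNetClassifier, evaluate, pgd_attack,
                          referable_labels, train_plain, train_robust)
from .diffusion import DenoisingDiffusion, train_denoiser
from .dvc import GuidanceConfig, generate_dvc_batch
from .evaluate import flip_rate_table, lesion_delta_report
from .phantom import balance_by_oversampling, generate_dataset
from .svc import SvcConfig, generate_svc_batch


@dataclass
class ExperimentConfig:
    seed: int = 0
    image_size: int = 32
    n_per_class: int = 64
    images_per_subject: int = 2
    T: int = 250
    diffusion_iters: int = 2500
    diffusion_channels: int = 8
    clf_epochs: int = 50
    robust_epochs: int = 80
    eps_train: float = 0.35        # l2 TRADES radius at this resolution
    lambdas: tuple = (0.7, 0.5, 0.3, 0.2)
    n_sweep_per_direction: int = 16
    n_attack_eval: int = 48
    svc_eps: float = 3.0           # l4 radius at this resolution
    run_svc: bool = True


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    dataset: object
    diffusion: DenoisingDiffusion
    plain: ConvNetClassifier
    robust: ConvNetClassifier
    clean_metrics: dict
    attack_metrics: dict
    sweep: dict                    # lambda_d -> direction -> list[CounterfactualResult]
    sweep_originals: dict          # direction -> (X, labels, subject_ids)
    flip_table: object
    distance_monotone_fraction: float
    lesion_deltas: dict            # direction -> median count deltas at default lambda
    identity: dict
    svc_flip_fraction: float | None = None
    extras: dict = field(default_factory=dict)


def _stack(images):
    return np.stack([im.pixels for im in images]).astype(np.float32)


def run_desk_experiment(cfg: ExperimentConfig | None = None, **overrides) -> ExperimentResult:
    cfg = cfg or ExperimentConfig(**overrides)
    seed = cfg.seed

    # data ------------------------------------------------------------------
    ds = generate_dataset(cfg.n_per_class, cfg.images_per_subject,
                          (0.75, 0.15, 0.10), seed=seed, modality="fundus",
                          image_size=cfg.image_size)
    balanced = balance_by_oversampling(ds)
    train_imgs = balanced.subset("train")
    X_tr = _stack(train_imgs)
    y_tr = referable_labels([im.label for im in train_imgs])
    val_imgs = ds.subset("val")
    X_va = _stack(val_imgs)
    y_va = referable_labels([im.label for im in val_imgs])
    test_imgs = ds.subset("test") + val_imgs
    X_te = _stack(test_imgs)
    y_te = referable_labels([im.label for im in test_imgs])

    # models ----------------------------------------------------------------
    diffusion = train_denoiser(train_imgs, schedule_T=cfg.T,
                               iterations=cfg.diffusion_iters,
                               base_channels=cfg.diffusion_channels,
                               rng_seed=seed)
    plain = train_plain(X_tr, y_tr, epochs=cfg.clf_epochs, rng_seed=seed)
    robust = train_robust(X_tr, y_tr, eps=cfg.eps_train, epochs=cfg.robust_epochs,
                          rng_seed=seed)
    classifiers = {"plain": plain, "robust": robust}
    clean = {m: evaluate(clf, X_te, y_te) for m, clf in classifiers.items()}

    # robustness under PGD at the training radius ---------------------------
    rng = np.random.default_rng([seed, 17])
    idx = rng.permutation(len(X_te))[:cfg.n_attack_eval]
    attack = {}
    for m, clf in classifiers.items():
        ok = np.ones(len(idx), dtype=bool)
        for rs in range(2):   # two restarts of a 20-step attack
            x_adv = pgd_attack(clf, X_te[idx], eps=cfg.eps_train, p=2.0, steps=20,
                               y=y_te[idx], rng=np.random.default_rng([seed, 19 + rs]))
            ok &= clf.predict(x_adv) == y_te[idx]
        attack[m] = float(ok.mean())

    # sweep pools: correctly classified originals per direction -------------
    pred = plain.predict(X_te)
    pools = {}
    for direction, want in (("healthy_to_diseased", 0), ("diseased_to_healthy", 1)):
        sel = [i for i in range(len(X_te))
               if y_te[i] == want and pred[i] == want][:cfg.n_sweep_per_direction]
        pools[direction] = (X_te[sel], np.array([test_imgs[i].label for i in sel]),
                           np.array([test_imgs[i].subject_id for i in sel]))

    sweep = {}
    for lam in cfg.lambdas:
        sweep[lam] = {}
        for direction, (X0, _, _) in pools.items():
            target = 1 if direction == "healthy_to_diseased" else 0
            gc = GuidanceConfig(target_class=target, lambda_d=lam, mode="cone",
                                seed=seed)
            sweep[lam][direction] = generate_dvc_batch(
                X0, target, diffusion, classifiers, gc)

    flip_table = flip_rate_table(sweep)

    # per-image distance monotonicity across the lambda grid ---------------
    lam_sorted = sorted(cfg.lambdas, reverse=True)
    mono = []
    for direction in pools:
        n = len(pools[direction][0])
        for i in range(n):
            dists = [sweep[lam][direction][i].l2_distance for lam in lam_sorted]
            mono.append(all(d2 > d1 for d1, d2 in zip(dists, dists[1:])))
    mono_frac = float(np.mean(mono)) if mono else float("nan")

    # lesion semantics + identity preservation at the default lambda -------
    lam0 = 0.5 if 0.5 in cfg.lambdas else cfg.lambdas[len(cfg.lambdas) // 2]
    deltas = {}
    for direction, (X0, _, _) in pools.items():
        cfs = sweep[lam0][direction]
        deltas[direction] = lesion_delta_report(
            [(X0[i], cfs[i].image) for i in range(len(X0))])

    identity = _identity_check(sweep[lam0], pools)

    svc_flip = None
    if cfg.run_svc:
        X0 = pools["healthy_to_diseased"][0]
        res = generate_svc_batch(X0, SvcConfig(target_class=1, eps=cfg.svc_eps,
                                               p=4.0, steps=50, seed=seed),
                                 classifiers)
        svc_flip = float(np.mean([r.flipped for r in res])) if len(res) else None

    return ExperimentResult(
        config=cfg, dataset=ds, diffusion=diffusion, plain=plain, robust=robust,
        clean_metrics=clean, attack_metrics=attack, sweep=sweep,
        sweep_originals=pools, flip_table=flip_table,
        distance_monotone_fraction=mono_frac, lesion_deltas=deltas,
        identity=identity, svc_flip_fraction=svc_flip)


def _identity_check(results_by_direction: dict, pools: dict) -> dict:
    """Mean distance DVC-to-own-original vs DVC-to-another subject's image
    of the same original class."""
    out = {}
    for direction, cfs in results_by_direction.items():
        X0, labels, subjects = pools[direction]
        own, other = [], []
        n = len(X0)
        if n < 2:
            continue
        for i in range(n):
            own.append(cfs[i].l2_distance)
            js = [j for j in range(n) if subjects[j] != subjects[i]]
            if not js:
                continue
            j = js[i % len(js)]
            other.append(float(np.linalg.norm((cfs[i].image - X0[j]).ravel())))
        out[direction] = {"own": float(np.mean(own)), "other": float(np.mean(other))}
    return out
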