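"""End-to-end orchestration: cohort data to group-level receptor inference.

Ties the stages together the way the clinical analysis runs: invert a few
control subjects under default priors, re-center the priors on their
average posterior (empirical prior calibration), invert every subject,
then ask the group-level questions — PEB/BMR effect probabilities per
receptor class, CVA separation, and individual classification with the
occipital-alpha confound adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortTable
from .forward import ForwardModel
from .group import build_design, bmr_search, classify, cva, peb_fit
from .inversion import (
    InversionConfig,
    Posterior,
    PriorDensity,
    calibrate_empirical_priors,
    default_priors,
    variational_laplace,
)
from .network import NetworkModel, build_default_network
from .params import OBS_LABELS

__all__ = ["invert_cohort", "receptor_effect_counts", "GroupAnalysis",
           "analyze_cohort"]


#: Cohort-scale inversion settings: forward differences and a moderate
#: iteration cap keep one subject's inversion to a couple of seconds at
#: negligible cost to group-level effect detection.
COHORT_INVERSION = InversionConfig(max_iter=40, tol=0.01, fd_scheme="forward")


def _restrict(post: Posterior, idx: np.ndarray) -> Posterior:
    """Marginal posterior over a subset of parameters."""
    return Posterior(
        mean=post.mean[idx],
        cov=post.cov[np.ix_(idx, idx)],
        free_energy=post.free_energy,
        trace=post.trace,
        r2=post.r2,
        labels=tuple(np.asarray(post.labels)[idx]),
    )


def invert_cohort(table: CohortTable, band=(20.0, 48.0),
                  net: NetworkModel | None = None,
                  config: InversionConfig | None = None,
                  model_config=None,
                  n_calibration: int = 3, seed: int = 0,
                  subject_ids=None) -> dict:
    """Invert every subject's CSD in one frequency band.

    Priors are first calibrated empirically: ``n_calibration`` control
    subjects, chosen at random, are inverted under the default priors and
    the prior mean is re-centered on their average posterior before all
    subjects (including those controls) are inverted.
    """
    net = net or build_default_network()
    config = config or COHORT_INVERSION
    rng = np.random.default_rng(seed)
    ids = list(subject_ids if subject_ids is not None else table.table["id"])
    groups = dict(zip(table.table["id"], table.table["group"]))

    def fit_one(sid, priors):
        fm = ForwardModel(net, table.lead_field, table.modes[sid].matrix,
                          model_config)
        cs = table.csd[sid].band(*band)
        return variational_laplace(cs, fm, priors=priors, config=config)

    base_fm = ForwardModel(
        net, table.lead_field, table.modes[ids[0]].matrix, model_config
    )
    base_prior = default_priors(base_fm)
    controls = [s for s in ids if groups[s] == "control"]
    cal_ids = list(
        rng.choice(controls, size=min(n_calibration, len(controls)),
                   replace=False)
    ) if controls else []
    if cal_ids:
        cal_posts = [fit_one(s, base_prior) for s in cal_ids]
        priors = calibrate_empirical_priors(cal_posts, base_prior)
    else:
        priors = base_prior
    posteriors = {s: fit_one(s, priors) for s in ids}
    return {"posteriors": posteriors, "priors": priors,
            "calibration_ids": cal_ids}


def receptor_effect_counts(prob: dict, labels, partition,
                           covariate: int = 2,
                           threshold: float = 0.95) -> dict:
    """Count parameters crossing the effect-probability threshold per
    receptor class for one covariate of the second-level design."""
    labels = list(labels)
    sets = {
        "NMDA": {labels[i] for i in partition.nmda},
        "AMPA": {labels[i] for i in partition.ampa},
        "GABAA": {labels[i] for i in partition.gabaa},
        "OTHER": {labels[i] for i in partition.other},
    }
    counts = {k: 0 for k in sets}
    for (cov, lab), p in prob.items():
        if cov != covariate or p <= threshold:
            continue
        for k, s in sets.items():
            if lab in s:
                counts[k] += 1
    return counts


@dataclass
class GroupAnalysis:
    peb_result: object
    counts: dict
    design: np.ndarray
    posteriors: dict
    cva_results: dict = field(default_factory=dict)
    classification: dict | None = None


def analyze_cohort(table: CohortTable, band=(2.0, 48.0),
                   net: NetworkModel | None = None,
                   config: InversionConfig | None = None,
                   model_config=None,
                   seed: int = 0, n_em_rounds: int = 1,
                   run_cva: bool = False,
                   run_classification: bool = False) -> GroupAnalysis:
    """Full pipeline on one cohort: inversions, PEB + BMR, optional CVA
    and classification.

    The default band spans 2-48 Hz: the slow NMDA channel kinetics are
    expressed at low frequencies, so including them is what makes NMDA
    parameters separable from AMPA weights at the first level.  After the
    initial inversions, ``n_em_rounds`` empirical-Bayes refinements
    re-invert every subject under the second-level conditional prior
    (prior mean X_i beta) — the standard EM treatment of the hierarchy,
    which consolidates weak but consistent group effects.  PEB/BMR
    operates on the neuronal parameters; observation parameters are
    excluded from the second-level effect search, matching the
    receptor-focused question.
    """
    net = net or build_default_network()
    config = config or COHORT_INVERSION
    inv = invert_cohort(table, band=band, net=net, config=config,
                        model_config=model_config, seed=seed)
    posteriors = inv["posteriors"]
    priors0 = inv["priors"]
    ids = list(table.table["id"])
    groups = table.groups()
    X = build_design(groups)
    spec = net.param_spec()
    n_idx = np.arange(spec.n_params)
    peb = peb_fit([_restrict(posteriors[s], n_idx) for s in ids], X)
    for _ in range(n_em_rounds):
        B = peb.beta_mean.reshape(X.shape[1], spec.n_params)
        for k, sid in enumerate(ids):
            mu = priors0.mean.copy()
            mu[: spec.n_params] = X[k] @ B
            pr = PriorDensity(mu, priors0.cov, priors0.labels)
            fm = ForwardModel(net, table.lead_field,
                              table.modes[sid].matrix, model_config)
            posteriors[sid] = variational_laplace(
                table.csd[sid].band(*band), fm, priors=pr, config=config
            )
        peb = peb_fit([_restrict(posteriors[s], n_idx) for s in ids], X)
    bmr = bmr_search(peb, covariates=(1, 2))
    part = spec.partition()
    counts = receptor_effect_counts(
        bmr.effect_probability, spec.labels, part, covariate=2
    )
    ga = GroupAnalysis(
        peb_result=bmr, counts=counts, design=X, posteriors=posteriors
    )
    if run_cva or run_classification:
        Y = np.stack([posteriors[s].mean[: spec.n_params] for s in ids])
        contrast = (groups == "nmdar").astype(float)
        for name, idx in (("NMDA", part.nmda), ("AMPA", part.ampa),
                          ("GABAA", part.gabaa)):
            try:
                ga.cva_results[name] = cva(Y, contrast, subset=idx)
            except ValueError:
                pass
        if run_classification and "NMDA" in ga.cva_results:
            w = np.zeros(spec.n_params)
            w[part.nmda] = ga.cva_results["NMDA"].canonical_vectors[:, 0]
            alpha = table.table["alpha_power"].to_numpy()
            ga.classification = classify(
                Y, w, groups, positive_label="nmdar", alpha_power=alpha
            )
    return ga
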