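"""Stochastic composition of augmentation methods and ratio bookkeeping.

Three policies combine a configured ordered set of K methods (default
order SSx-WD-MW-GN, with SSx = SS2):

``one``     apply exactly one method, chosen uniformly at random;
``all``     apply all K methods consecutively, in order;
``random``  walk the methods in order and apply method k iff a uniform
            draw u_k exceeds its threshold p_k — i.e. p_k is a *skip*
            probability (apply with probability 1 - p_k).  At the default
            p_k = 0.5 both readings coincide.

The amount of augmentation is the ratio R = generated / original records:
a dataset of 364 records at R = 9 gains 3276 generated records for a
total of 3640.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import augment_basic, augment_sim
from .errors import ConfigurationError, ParameterError
from .signal_model import LabeledDataset, MultichannelSignal

__all__ = [
    "AugmentationSpec",
    "AugmentorPolicy",
    "apply_spec",
    "apply_policy",
    "build_augmented_dataset",
    "default_method_order",
]

_SEED_MOD = 2**31  # keep derived seeds comfortably inside int32


@dataclass(frozen=True)
class AugmentationSpec:
    """One augmentation method plus its (seed-free) parameters.

    ``method`` is one of ``gn``, ``mw``, ``wd``, ``ss1``, ``ss2``;
    ``params`` holds keyword arguments for the matching ``*Params``
    dataclass, minus ``rng_seed`` which is injected at application time.
    """

    method: str
    params: Mapping = field(default_factory=dict)

    def __post_init__(self):
        if self.method not in _DISPATCH:
            raise ConfigurationError(
                f"unknown augmentation method {self.method!r}; "
                f"expected one of {sorted(_DISPATCH)}"
            )
        object.__setattr__(self, "params", dict(self.params))


def _run_gn(x, params, seed):
    return augment_basic.gaussian_noise(
        x, augment_basic.GNParams(rng_seed=seed, **params)
    )


def _run_mw(x, params, seed):
    return augment_basic.magnitude_warp(
        x, augment_basic.MWParams(rng_seed=seed, **params)
    )


def _run_wd(x, params, seed):
    # WD is deterministic: the randomness lives in the choice of
    # (wavelet, level, b), which is selected once per dataset by grid search.
    return augment_basic.wavelet_perturb(x, augment_basic.WDParams(**params))


def _run_ss1(x, params, seed):
    return augment_sim.simulate_ss1(
        x, augment_sim.SS1Params(rng_seed=seed, **params)
    )


def _run_ss2(x, params, seed):
    return augment_sim.simulate_ss2(
        x, augment_sim.SS2Params(rng_seed=seed, **params)
    )


_DISPATCH = {
    "gn": _run_gn,
    "mw": _run_mw,
    "wd": _run_wd,
    "ss1": _run_ss1,
    "ss2": _run_ss2,
}


def apply_spec(
    x: MultichannelSignal, spec: AugmentationSpec, seed: int
) -> MultichannelSignal:
    """Apply one augmentation method to a record with the given seed."""
    return _DISPATCH[spec.method](x, spec.params, int(seed) % _SEED_MOD)


def default_method_order(ssx: str = "ss2") -> list[AugmentationSpec]:
    """The canonical SSx-WD-MW-GN method list with the selected defaults."""
    if ssx not in ("ss1", "ss2"):
        raise ConfigurationError("ssx must be 'ss1' or 'ss2'")
    return [
        AugmentationSpec(ssx),
        AugmentationSpec("wd"),
        AugmentationSpec("mw"),
        AugmentationSpec("gn"),
    ]


@dataclass(frozen=True)
class AugmentorPolicy:
    """A composition policy over an ordered method list.

    ``probabilities`` are the per-method skip thresholds of ``random``
    mode (default 0.5 each).  Pass ``apply_probabilities`` instead to use
    the intuitive "apply with probability q" reading (stored as 1 - q).
    """

    mode: str
    methods: Sequence[AugmentationSpec] = field(default_factory=default_method_order)
    probabilities: Sequence[float] | None = None
    apply_probabilities: Sequence[float] | None = None
    rng_seed: int = 0

    def __post_init__(self):
        if self.mode not in ("one", "all", "random"):
            raise ConfigurationError(
                f"mode must be 'one', 'all' or 'random', got {self.mode!r}"
            )
        if not self.methods:
            raise ConfigurationError("policy needs a non-empty method list")
        object.__setattr__(self, "methods", tuple(self.methods))
        if self.apply_probabilities is not None:
            if self.probabilities is not None:
                raise ConfigurationError(
                    "give either probabilities (skip thresholds) or "
                    "apply_probabilities, not both"
                )
            probs = tuple(1.0 - q for q in self.apply_probabilities)
        elif self.probabilities is not None:
            probs = tuple(float(p) for p in self.probabilities)
        else:
            probs = tuple(0.5 for _ in self.methods)
        if len(probs) != len(self.methods):
            raise ConfigurationError(
                f"{len(probs)} probabilities for {len(self.methods)} methods"
            )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigurationError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "probabilities", probs)
        object.__setattr__(self, "apply_probabilities", None)


def _streams(seed_seq: np.random.SeedSequence, k: int):
    """One selection stream plus k per-method seeds from a seed sequence.

    Method seeds are independent of the selection stream, so ``random``
    mode with every method applied reproduces ``all`` mode bit-for-bit.
    """
    children = seed_seq.spawn(k + 1)
    selection_rng = np.random.default_rng(children[-1])
    method_seeds = [int(c.generate_state(1)[0]) % _SEED_MOD for c in children[:-1]]
    return selection_rng, method_seeds


def apply_policy(
    x: MultichannelSignal,
    pol: AugmentorPolicy,
    seed_seq: np.random.SeedSequence | None = None,
) -> tuple[MultichannelSignal, list[str]]:
    """Apply a composition policy to one record.

    Returns the augmented record and the realized method-tag list (the
    audit log of what actually ran).  Deterministic given the policy's
    seed (or an explicit ``seed_seq`` override).
    """
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(pol.rng_seed)
    selection_rng, method_seeds = _streams(seed_seq, len(pol.methods))
    realized: list[str] = []
    out = x
    if pol.mode == "one":
        k = int(selection_rng.integers(len(pol.methods)))
        out = apply_spec(out, pol.methods[k], method_seeds[k])
        realized.append(pol.methods[k].method)
    elif pol.mode == "all":
        for spec, seed in zip(pol.methods, method_seeds):
            out = apply_spec(out, spec, seed)
            realized.append(spec.method)
    else:  # random
        u = selection_rng.uniform(size=len(pol.methods))
        for k, (spec, seed) in enumerate(zip(pol.methods, method_seeds)):
            if u[k] > pol.probabilities[k]:
                out = apply_spec(out, spec, seed)
                realized.append(spec.method)
    return out, realized


def build_augmented_dataset(
    ds: LabeledDataset,
    policy: "AugmentorPolicy | AugmentationSpec",
    ratio: int,
    master_seed: int | None = None,
) -> LabeledDataset:
    """Originals plus ``ratio`` generated records per original.

    Generated records inherit their source's label, repetition and
    subject (the augmentation contract: the label never changes) and are
    tagged ``origin='augmented'`` with the realized method lineage.  Each
    (record, copy) pair gets an independent RNG stream derived from the
    master seed, so results do not depend on processing order.
    ``len(output) == (ratio + 1) * len(ds)``.
    """
    if ratio < 0:
        raise ParameterError(f"augmentation ratio must be >= 0, got {ratio}")
    if master_seed is None:
        master_seed = (
            policy.rng_seed if isinstance(policy, AugmentorPolicy) else 0
        )
    records = list(ds.records)
    for j, (sig, meta) in enumerate(ds):
        for i in range(ratio):
            ss = np.random.SeedSequence(master_seed, spawn_key=(j, i))
            if isinstance(policy, AugmentorPolicy):
                aug, realized = apply_policy(sig, policy, seed_seq=ss)
            else:
                seed = int(ss.generate_state(1)[0]) % _SEED_MOD
                aug = apply_spec(sig, policy, seed)
                realized = [policy.method]
            # 'random' mode may skip every method; the copy still counts
            # toward R, and its lineage records the pass-through.
            records.append((aug, meta.derived(realized or ["identity"])))
    return LabeledDataset(records)
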