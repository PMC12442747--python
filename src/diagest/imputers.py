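"""Registry of imputation rules for event-affected or absent results.

An imputer maps a subject record to a positive/negative result. The
hypothetical strategy always needs one (it predicts the result had the
event not occurred); the diagnostic-policy and setback strategies need one
only when the quantity they rely on (the index result, respectively the
true condition) is absent.

Built-ins:

``constant:positive`` / ``constant:negative``
    Always return the fixed result.
``bernoulli:<p>``
    Positive with probability ``p`` — requires a seeded random generator,
    so results are reproducible run to run.
``oracle``
    Return the record's stored counterfactual result (the result had no
    event occurred). Only simulated data carries counterfactuals; on real
    data this imputer fails loudly.

Covariate-model imputation is an extension point: register a factory with
:func:`register_imputer` and reference it by name from the estimand spec.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np

from .errors import ImputationError
from .study_data import Result, SubjectRecord

#: an imputer takes (record, rng) and returns POSITIVE or NEGATIVE
Imputer = Callable[[SubjectRecord, Optional[np.random.Generator]], Result]

_REGISTRY: dict[str, Callable[[Optional[str]], Imputer]] = {}


def register_imputer(name: str, factory: Callable[[Optional[str]], Imputer]) -> None:
    """Register an imputer factory under ``name`` (``name[:arg]`` in specs)."""
    _REGISTRY[name] = factory


def get_imputer(spec: str) -> Imputer:
    """Resolve an imputer spec string such as ``constant:positive``."""
    name, _, arg = spec.partition(":")
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise ImputationError(
            f"unknown imputer '{name}' (registered: {sorted(_REGISTRY)})"
        ) from None
    return factory(arg or None)


def _constant_factory(arg: Optional[str]) -> Imputer:
    if arg not in ("positive", "negative"):
        raise ImputationError("constant imputer needs ':positive' or ':negative'")
    fixed = Result(arg)

    def impute(record: SubjectRecord, rng: Optional[np.random.Generator]) -> Result:
        return fixed

    return impute


def _bernoulli_factory(arg: Optional[str]) -> Imputer:
    try:
        p = float(arg)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        raise ImputationError("bernoulli imputer needs ':<p>' with p in [0, 1]")
    if not 0.0 <= p <= 1.0:
        raise ImputationError(f"bernoulli probability must be in [0, 1], got {p}")

    def impute(record: SubjectRecord, rng: Optional[np.random.Generator]) -> Result:
        if rng is None:
            raise ImputationError(
                "bernoulli imputer requires a seeded random generator; "
                "pass a seed through the engine options"
            )
        return Result.POSITIVE if rng.random() < p else Result.NEGATIVE

    return impute


def _oracle_factory(arg: Optional[str]) -> Imputer:
    def impute(record: SubjectRecord, rng: Optional[np.random.Generator]) -> Result:
        cf = record.counterfactual_result
        if cf is Result.ABSENT:
            raise ImputationError(
                f"subject {record.subject_id}: oracle imputer needs a stored "
                "counterfactual result (simulated data only)"
            )
        return cf

    return impute


register_imputer("constant", _constant_factory)
register_imputer("bernoulli", _bernoulli_factory)
register_imputer("oracle", _oracle_factory)
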