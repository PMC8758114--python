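"""End-to-end glue: labeled T1/T2 pairs -> registered composites -> features.

Convenience wrappers that chain registration, composite construction and
backbone feature extraction the way the full tool runs them, used by the
command-line interface, the benchmark and the tests.
"""

from __future__ import annotations

import numpy as np

from .composite import build_composite, prepare_for_backbone
from .features import FeatureMatrix, extract_features, get_backbone
from .registration import ESConfig, RegistrationResult, register_pair

__all__ = ["pairs_to_features", "registered_composite"]


def registered_composite(t1: np.ndarray, t2: np.ndarray,
                         es: ESConfig | None = None, bins: int = 50,
                         pyramid_levels: int = 3):
    """Register T2 onto T1 and build the 3-channel composite.

    Returns ``(composite, registration_result)``; the composite is built
    whether or not the registration converged, mirroring the tool's
    behavior of flagging rather than hard-failing difficult pairs.
    """
    from .registration import transform_image

    result: RegistrationResult = register_pair(
        t1, t2, es=es, bins=bins, pyramid_levels=pyramid_levels)
    t2_reg = transform_image(t2, result.transform)
    comp = build_composite(t1, t2_reg)
    return comp, result


def pairs_to_features(pairs, backbone: str = "ResNet18",
                      register: bool = True, es: ESConfig | None = None,
                      bins: int = 50, pyramid_levels: int = 3,
                      batch_size: int = 8, seed: int = 0,
                      drop_failed: bool = False) -> FeatureMatrix:
    """Run labeled pairs through the image pipeline into a feature matrix.

    ``pairs`` is any sequence of objects with ``t1``, ``t2`` and ``label``
    attributes (phantom records or loaded dataset pairs).  With
    ``drop_failed`` the pairs whose registration did not converge are
    removed, as the study protocol drops non-converging registrations.
    """
    spec = get_backbone(backbone)
    composites = []
    labels = []
    ids = []
    for i, p in enumerate(pairs):
        if register:
            comp, res = registered_composite(
                p.t1, p.t2, es=es, bins=bins, pyramid_levels=pyramid_levels)
            if drop_failed and not res.converged:
                continue
        else:
            comp = build_composite(p.t1, p.t2)
        composites.append(prepare_for_backbone(comp, spec.input_size))
        labels.append(p.label)
        ids.append(getattr(p, "pair_id", i))
    return extract_features(composites, spec, batch_size=batch_size,
                            seed=seed, sample_ids=ids, labels=labels)
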