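"""Normalized Shannon entropy of a composition.

Both the family entropy of a genomic miRNA cluster (E_fam) and the cluster
entropy of a network module (E_c) are the same quantity applied to different
label sets: the Shannon entropy of the label composition, normalized by
``ln(n_labels)`` so the value lies in [0, 1].

* 0  — all items carry the same label;
* 1  — every item carries a distinct label (uniform composition over as many
  labels as items).

For a single label the normalizing factor ``1/ln(1)`` is undefined; the value
is defined as the limit 0, consistent with the "all from one family/cluster"
reading.
"""

from __future__ import annotations

import math
from collections import Counter
from collections.abc import Iterable, Mapping
from typing import Hashable

__all__ = ["normalized_entropy", "composition_probs"]


def composition_probs(labels: Iterable[Hashable]) -> dict[Hashable, float]:
    """Relative frequency of each label. Empty input gives an empty map."""
    counts = Counter(labels)
    total = sum(counts.values())
    return {lab: c / total for lab, c in counts.items()}


def normalized_entropy(labels: Iterable[Hashable] | Mapping[Hashable, float]) -> float:
    """Shannon entropy of the label composition, normalized by ln(n_labels).

    Parameters
    ----------
    labels
        Either an iterable of label values (one per item) or a mapping
        label -> probability summing to 1.

    Returns
    -------
    float in [0, 1]; exactly 0.0 when there is a single distinct label.

    Raises
    ------
    ValueError
        If no labels are supplied.
    """
    if isinstance(labels, Mapping):
        probs = [p for p in labels.values() if p > 0]
    else:
        probs = list(composition_probs(labels).values())
    if not probs:
        raise ValueError("entropy of an empty composition is undefined")
    n = len(probs)
    if n == 1:
        return 0.0
    h = -sum(p * math.log(p) for p in probs)
    value = h / math.log(n)
    # guard against tiny float excursions outside [0, 1]
    return min(1.0, max(0.0, value))
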