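"""Isoform-space arithmetic for mutually exclusive splicing clusters.

A transcript picks exactly one variant from each mutually exclusive cluster
and independently includes or skips each optional exon, so the potential
isoform count is the product of cluster sizes times 2 per optional exon.
For Drosophila melanogaster Dscam-hv: 12 x 48 x 33 x 2 = 38,016 ectodomain/
transmembrane combinations, and 4 x 38,016 = 152,064 counting the two
optional endodomain exons.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import ValidationError


@dataclass
class ClusterSizes:
    sizes: tuple[int, ...]
    n_optional: int = 0

    def __post_init__(self):
        self.sizes = tuple(int(s) for s in self.sizes)
        if not self.sizes:
            raise ValidationError("need at least one cluster")
        if any(s < 1 for s in self.sizes):
            raise ValidationError("every cluster size must be >= 1")
        if self.n_optional < 0:
            raise ValidationError("n_optional must be >= 0")


def isoform_space(clusters: ClusterSizes | Sequence[int],
                  n_optional: int | None = None) -> int:
    """Exact integer count of potential splice isoforms."""
    if not isinstance(clusters, ClusterSizes):
        clusters = ClusterSizes(tuple(clusters),
                                0 if n_optional is None else n_optional)
    elif n_optional is not None:
        raise ValidationError("n_optional given twice")
    out = 1
    for s in clusters.sizes:
        out *= s
    return out * (2 ** clusters.n_optional)
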