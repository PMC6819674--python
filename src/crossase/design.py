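"""The reciprocal-cross layout: which parents form which cross, which
offspring pools belong to which cross.

Two breeds — Korean native pig (KNP) and Landrace — are crossed both ways:
KNP dam x Landrace sire, and Landrace dam x KNP sire.  Each cross
contributes one male and one female offspring pool.  Cross labels follow
the dam-first convention ("KxL" = KNP dam) by default; ``default_design``
takes a flag to flip it, and every downstream classification is symmetric
under the swap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

KNP = "KNP"
LANDRACE = "Landrace"
BREEDS = (KNP, LANDRACE)


@dataclass(frozen=True)
class Cross:
    """One cross: a dam and a sire (parent sample names) and its pools."""

    cross_id: str
    dam: str
    sire: str
    pool_ids: tuple[str, ...]


@dataclass(frozen=True)
class CrossDesign:
    crosses: tuple[Cross, Cross]
    breed_of_sample: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.crosses) != 2:
            raise ValueError("a reciprocal design needs exactly two crosses")
        c1, c2 = self.crosses
        for c in self.crosses:
            for parent in (c.dam, c.sire):
                if parent not in self.breed_of_sample:
                    raise ValueError(f"parent {parent!r} missing from breed_of_sample")
            if self.breed_of_sample[c.dam] == self.breed_of_sample[c.sire]:
                raise ValueError(f"cross {c.cross_id}: dam and sire share a breed")
        if self.breed_of_sample[c1.dam] != self.breed_of_sample[c2.sire] or (
            self.breed_of_sample[c1.sire] != self.breed_of_sample[c2.dam]
        ):
            raise ValueError("crosses are not reciprocal (dam/sire breeds must swap)")
        pools = [p for c in self.crosses for p in c.pool_ids]
        if len(pools) != len(set(pools)):
            raise ValueError("pool ids must be unique across crosses")
        if set(self.breed_of_sample.values()) - set(BREEDS):
            raise ValueError(f"breeds must be among {BREEDS}")

    @property
    def pool_ids(self) -> tuple[str, ...]:
        return tuple(p for c in self.crosses for p in c.pool_ids)

    @property
    def parent_samples(self) -> tuple[str, ...]:
        seen: list[str] = []
        for c in self.crosses:
            for p in (c.dam, c.sire):
                if p not in seen:
                    seen.append(p)
        return tuple(seen)

    def cross_of_pool(self, pool_id: str) -> Cross:
        for c in self.crosses:
            if pool_id in c.pool_ids:
                return c
        raise KeyError(f"pool {pool_id!r} not in any cross of the design")

    def sire_breed(self, pool_id: str) -> str:
        return self.breed_of_sample[self.cross_of_pool(pool_id).sire]

    def dam_breed(self, pool_id: str) -> str:
        return self.breed_of_sample[self.cross_of_pool(pool_id).dam]

    def swapped(self) -> "CrossDesign":
        """The design with dam and sire exchanged in both crosses."""
        return CrossDesign(
            tuple(Cross(c.cross_id, c.sire, c.dam, c.pool_ids) for c in self.crosses),
            dict(self.breed_of_sample),
        )

    def to_dict(self) -> dict:
        return {
            "crosses": [
                {"cross_id": c.cross_id, "dam": c.dam, "sire": c.sire,
                 "pool_ids": list(c.pool_ids)}
                for c in self.crosses
            ],
            "breed_of_sample": dict(self.breed_of_sample),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CrossDesign":
        crosses = tuple(
            Cross(c["cross_id"], c["dam"], c["sire"], tuple(c["pool_ids"]))
            for c in d["crosses"]
        )
        return cls(crosses, dict(d["breed_of_sample"]))


PARENT_SAMPLES = ("KNP_M", "KNP_F", "LR_M", "LR_F")

PARENT_BREEDS = {
    "KNP_M": KNP,
    "KNP_F": KNP,
    "LR_M": LANDRACE,
    "LR_F": LANDRACE,
    # joint (same-breed pooled) samples used by mapping strategy II
    KNP: KNP,
    LANDRACE: LANDRACE,
}


def default_design(sire_first: bool = False) -> CrossDesign:
    """The KNP x Landrace reciprocal design with one pool per sex per cross.

    With the default dam-first convention, cross "KxL" has a KNP dam and a
    Landrace sire.  ``sire_first=True`` flips the reading of the labels.
    """
    if sire_first:
        kxl = Cross("KxL", dam="LR_F", sire="KNP_M", pool_ids=("KxL_M", "KxL_F"))
        lxk = Cross("LxK", dam="KNP_F", sire="LR_M", pool_ids=("LxK_M", "LxK_F"))
    else:
        kxl = Cross("KxL", dam="KNP_F", sire="LR_M", pool_ids=("KxL_M", "KxL_F"))
        lxk = Cross("LxK", dam="LR_F", sire="KNP_M", pool_ids=("LxK_M", "LxK_F"))
    return CrossDesign((kxl, lxk), dict(PARENT_BREEDS))
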