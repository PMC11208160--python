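"""Target/donor site geometry shared by all stages.

An insertion site read on the top strand is the fusion of a left segment
(LT, 9 nt, recognized by the LTG loop segment) and a right segment (RT,
4–7 nt, recognized by the RTG) that overlap on the 2-nt core:

    site length = ltg_len + rtg_len - 2        (11 nt for the short RTG,
                                                 14 nt for the 7-nt RTG)
    core        = site[7:9]                    (positions 8–9, 1-based)

Pairing model: the LTG base-pairs with the *bottom* strand antiparallel,
hence reads identically to the top strand (LTG == site[0:9]); the RTG
base-pairs with the *top* strand, hence is its reverse complement
(RTG == revcomp(site[7:7+rtg_len])). The donor site and its LDG/RDG follow
the same geometry. In a concordance matrix this puts bottom-strand guides on
ascending diagonals with positive sign and top-strand guides on
anti-diagonals with negative sign.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import revcomp

__all__ = ["TargetGeometry", "GeometryError"]


class GeometryError(ValueError):
    """Guides and site disagree with the declared geometry."""


@dataclass(frozen=True)
class TargetGeometry:
    ltg_len: int = 9
    rtg_len: int = 4
    core: str = "CT"
    core_start: int = 7  # 0-based in the site; positions 8-9 one-based

    def __post_init__(self) -> None:
        if not 4 <= self.rtg_len <= 7:
            raise GeometryError("rtg_len must be in 4..7")
        if self.core_start + len(self.core) != self.ltg_len:
            raise GeometryError("core must sit at the LT/RT overlap")

    @property
    def site_length(self) -> int:
        return self.ltg_len + self.rtg_len - len(self.core)

    def guides_from_site(self, site: str) -> tuple[str, str]:
        """Left/right guide sequences encoding ``site`` (top strand)."""
        if len(site) < self.site_length:
            raise GeometryError(
                f"site of length {len(site)} < {self.site_length}")
        left = site[: self.ltg_len]
        right = revcomp(site[self.core_start : self.core_start + self.rtg_len])
        return left, right

    def site_from_guides(self, left_guide: str, right_guide: str) -> str:
        """Guide-encoded expected top-strand site; raises if the two guides
        disagree on the core overlap."""
        if len(left_guide) != self.ltg_len or len(right_guide) != self.rtg_len:
            raise GeometryError("guide lengths disagree with geometry")
        right_site = revcomp(right_guide)  # top-strand RT incl. core
        overlap = self.ltg_len - self.core_start
        if left_guide[self.core_start :] != right_site[:overlap]:
            raise GeometryError("left/right guides disagree on the core")
        return left_guide + right_site[overlap:]

    def core_of(self, site: str) -> str:
        return site[self.core_start : self.core_start + len(self.core)]

    def check_guides(self, left_guide: str, right_guide: str) -> bool:
        """True when both guides encode the geometry's core."""
        try:
            site = self.site_from_guides(left_guide, right_guide)
        except GeometryError:
            return False
        return self.core_of(site) == self.core
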