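"""Spectrum-source labels (MS1, or MS2 for one isolation window)."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Source", "MS1"]


@dataclass(frozen=True, order=True)
class Source:
    """Identifies which scan series of a run a grid or vector came from.

    Ordering is the canonical concatenation order: MS1 first, then MS2
    windows ascending by window index.
    """

    level: int  # 1 or 2
    window: int = -1  # isolation-window index for MS2, -1 for MS1

    def __post_init__(self) -> None:
        if self.level not in (1, 2):
            raise ValueError(f"ms level must be 1 or 2, got {self.level}")
        if self.level == 2 and self.window < 0:
            raise ValueError("MS2 source requires a window index")
        if self.level == 1 and self.window != -1:
            raise ValueError("MS1 source carries no window index")

    def __str__(self) -> str:
        return "ms1" if self.level == 1 else f"ms2_w{self.window}"

    @classmethod
    def ms2(cls, window: int) -> "Source":
        return cls(2, window)

    @classmethod
    def parse(cls, text: str) -> "Source":
        if text == "ms1":
            return MS1
        if text.startswith("ms2_w"):
            return cls(2, int(text[len("ms2_w"):]))
        raise ValueError(f"not a spectrum source label: {text!r}")


MS1 = Source(1)
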