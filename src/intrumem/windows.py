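"""Scene-relative time windows.

Three windows summarise the BOLD response to one film scene: the first
6 s of the scene, the remaining scene duration, and the 12 s following
the scene's conclusion.  Windows are defined in seconds relative to the
scene onset/offset; sampling onto the TR grid lives in
:mod:`intrumem.features`.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Class labels used throughout the package.
FLASHBACK = "flashback"
POTENTIAL = "potential"

#: Canonical window order; flashback effect triples follow this order.
WINDOW_TAGS = ("initial6", "remainder", "post12")


@dataclass(frozen=True)
class WindowDefinition:
    """A half-open time interval anchored to a scene.

    Parameters
    ----------
    tag:
        Window name, one of :data:`WINDOW_TAGS` for the standard set.
    start_anchor, end_anchor:
        ``"onset"`` or ``"offset"`` — which scene landmark each bound is
        relative to.
    start_offset, end_offset:
        Seconds added to the anchor.
    clip_to_scene:
        If True the window end is additionally capped at the scene
        offset (used by ``initial6`` so that for scenes shorter than 6 s
        the window never spills past the scene).
    """

    tag: str
    start_anchor: str
    start_offset: float
    end_anchor: str
    end_offset: float
    clip_to_scene: bool = False

    def bounds(self, onset: float, duration: float) -> tuple[float, float]:
        """Absolute ``[start, end)`` bounds in seconds for one scene."""
        offset = onset + duration
        start = (onset if self.start_anchor == "onset" else offset) + self.start_offset
        end = (onset if self.end_anchor == "onset" else offset) + self.end_offset
        if self.clip_to_scene:
            end = min(end, offset)
        return start, max(start, end)


INITIAL6 = WindowDefinition("initial6", "onset", 0.0, "onset", 6.0, clip_to_scene=True)
REMAINDER = WindowDefinition("remainder", "onset", 6.0, "offset", 0.0)
POST12 = WindowDefinition("post12", "offset", 0.0, "offset", 12.0)

#: The standard three-window set, in :data:`WINDOW_TAGS` order.
SCENE_WINDOWS = (INITIAL6, REMAINDER, POST12)
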