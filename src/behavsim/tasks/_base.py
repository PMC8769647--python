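"""Fixture protocol shared by the task library."""

from __future__ import annotations

from ..engine import TaskDefinition
from ..virtual_io import VirtualBoard


class Fixture:
    """A runnable bundle: task definition + hardware wiring + input drive.

    ``build`` declares the virtual channels the task uses on ``board`` and
    returns the task definition.  ``drive`` binds stimulus scripts and/or
    attaches closed-loop agents to a constructed engine; it is called before
    the run starts and may schedule input edges for the whole run or hook
    state listeners that inject edges as the session unfolds.
    ``params`` always carries ``duration_ms`` in addition to the fixture's
    ``default_params``.
    """

    name: str = ""
    description: str = ""
    default_params: dict = {}
    default_duration_ms: int = 10_000

    def build(self, board: VirtualBoard, params: dict) -> TaskDefinition:
        raise NotImplementedError

    def drive(self, engine, params: dict, seed: int) -> None:
        """Default: no external drive (task runs on timers alone)."""
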