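"""The introductory worked example: press a button three times, LED lights 1 s.

Two states: ``wait_for_press`` counts presses (the counter resets whenever the
state is re-entered); on the third press the machine moves to ``LED_on``,
whose entry handler lights the LED and arms a timed transition back after
1000 ms; its exit handler turns the LED off.  Presses during ``LED_on`` have
no effect.
"""

from __future__ import annotations

from ..engine import TaskDefinition
from ..virtual_io import VirtualBoard, make_square_wave
from ._base import Fixture


def button_led_task() -> TaskDefinition:
    def wait_for_press(run, event):
        if event == "entry":
            run.v.press_n = 0
        elif event == "press":
            run.v.press_n += 1
            if run.v.press_n == run.v.press_threshold:
                run.goto_state("LED_on")

    def led_on(run, event):
        if event == "entry":
            run.hw.LED.on()
            run.timed_goto_state("wait_for_press", run.v.LED_duration_ms)
        elif event == "exit":
            run.hw.LED.off()

    return TaskDefinition(
        name="button_led",
        states=("wait_for_press", "LED_on"),
        events=("press",),
        initial_state="wait_for_press",
        behaviour={"wait_for_press": wait_for_press, "LED_on": led_on},
        variables={"press_n": 0, "press_threshold": 3, "LED_duration_ms": 1000},
    )


class ButtonLedFixture(Fixture):
    name = "button-led"
    description = "three button presses turn an LED on for 1 s"
    default_params = {"press_hz": 1.0}
    default_duration_ms = 10_000

    def build(self, board: VirtualBoard, params: dict) -> TaskDefinition:
        board.digital_input("button", rising_event="press")
        board.digital_output("LED")
        return button_led_task()

    def drive(self, engine, params: dict, seed: int) -> None:
        # Button edges as a square wave: one press (rising edge) per period.
        edges = make_square_wave(params["press_hz"], params["duration_ms"])
        engine.board["button"].play(edges)
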