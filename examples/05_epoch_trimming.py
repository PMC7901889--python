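"""Duration standardization of artifact-free epochs.

Shows the trimming rules that map a subject's clean epochs onto the
standard analyzed durations of 240, 180 or 160 seconds.
"""

from obscor import Epoch, select_and_trim_epochs
from obscor.errors import InsufficientDataError

T = 0.004  # 250 Hz


def seconds(s):
    return int(round(s / T))


cases = {
    "one 300 s epoch": [Epoch(0, seconds(300))],
    "one 200 s epoch": [Epoch(0, seconds(200))],
    "120 s + 100 s epochs": [Epoch(0, seconds(120)),
                             Epoch(seconds(130), seconds(230))],
    "90 s + 75 s epochs": [Epoch(0, seconds(90)),
                           Epoch(seconds(100), seconds(175))],
    "90 s + 60 s epochs": [Epoch(0, seconds(90)),
                           Epoch(seconds(100), seconds(160))],
}

for name, epochs in cases.items():
    try:
        out = select_and_trim_epochs(epochs, T)
        total = sum(e.duration(T) for e in out)
        segs = ", ".join(f"{e.duration(T):.0f} s" for e in out)
        print(f"{name:24s} -> {total:5.0f} s total ({segs})")
    except InsufficientDataError as exc:
        print(f"{name:24s} -> excluded ({exc})")
print("-> analyzed durations are standardized to 240 / 180 / 160 s;")
print("   subjects whose two longest epochs fall short of 160 s are")
print("   excluded from the analysis.")
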