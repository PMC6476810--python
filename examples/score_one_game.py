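"""Score two games against a reference path (the worked example).

The reference is a level-3 game tapped at 1, 2, 3 s.  Game B is a level-2
game tapped more slowly (1.5, 3.0 s) and therefore right-censored at the
reference's extra jewel; game C matches the reference's level but takes
twice as long per tap.  Both must score below the reference's unit hazard
ratio, and C below B.
"""

from tapsurv import cox_fit, encode_pair, km_curve
from tapsurv.simulate import fig2_fixture

reference, game_b, game_c = fig2_fixture()

print("Kaplan-Meier curve of the reference (level 3, taps at 1, 2, 3 s):")
km = km_curve(reference)
for t, s in zip(km.times, km.survival):
    print(f"  S({t:.0f}s) = {s:.3f}")

for name, game in [("reference", reference), ("B", game_b), ("C", game_c)]:
    est = cox_fit(encode_pair(game, reference), game=game)
    print(f"game {name:9s} level {game.level}  "
          f"log HR = {est.log_hr:+.3f} (se {est.se:.3f})  HR = {est.hr:.3f}")
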