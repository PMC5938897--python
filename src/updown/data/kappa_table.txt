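# kappa correction factors, keyed by the six-response window
# (pre-change trial, first change, four subsequent trials).
# Maximum-likelihood values, probit model, spread = ladder step.
# Regenerate with: python -m updown.kappa
OXOOOO	-0.547046
OXOOOX	-1.250123
OXOOXO	+0.372007
OXOOXX	-0.168652
OXOXOO	+0.021541
OXOXOX	-0.500000
OXOXXO	+1.168652
OXOXXX	+0.610788
OXXOOO	-0.295915
OXXOOX	-0.831348
OXXOXO	+0.831348
OXXOXX	+0.295915
OXXXOO	+0.500000
OXXXOX	-0.043148
OXXXXO	+1.603423
OXXXXX	+0.893064
XOOOOO	-0.893064
XOOOOX	-1.603423
XOOOXO	+0.043148
XOOOXX	-0.500000
XOOXOO	-0.295915
XOOXOX	-0.831348
XOOXXO	+0.831348
XOOXXX	+0.295915
XOXOOO	-0.610788
XOXOOX	-1.168652
XOXOXO	+0.500000
XOXOXX	-0.021541
XOXXOO	+0.168652
XOXXOX	-0.372007
XOXXXO	+1.250123
XOXXXX	+0.547046
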