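# Structural fallback recipe table for the Potions Task (synthetic).
# The two discovery trajectories, tier ladder and crossover follow the task's
# published structure; the exact tier-2/3 triads are NOT ground truth from the
# original game -- they are the structural fallback: each tier-k item combines
# the tier-(k-1) item of its trajectory with two same-trajectory basics, and
# the crossover combines both tier-3 terminals with the highest-scoring basic.
product,trajectory,tier,innovation_score,tier_score,ingredients
a1,basic_a,0,6,0,
a2,basic_a,0,8,0,
a3,basic_a,0,10,0,
b1,basic_b,0,6,0,
b2,basic_b,0,8,0,
b3,basic_b,0,10,0,
1a,a,1,48,48,a1;a2;a3
1b,b,1,48,48,b1;b2;b3
2a,a,2,109,109,1a;a1;a2
2b,b,2,109,109,1b;b1;b2
3a,a,3,188,188,2a;a2;a3
3b,b,3,188,188,2b;b2;b3
x,crossover,4,358,358,3a;3b;a3
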