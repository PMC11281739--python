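"""Simulate a synthetic hospital-episode cohort for back-pain care.

Generates practice registers (with an IMD decile mixture per practice) and
five years of elective episodes, then prints the cohort's shape.
"""

from backvalue import SimulationConfig, generate_episodes, generate_registers

cfg = SimulationConfig(seed=42)  # 40 practices, 2015/16-2019/20
registers = generate_registers(cfg)
episodes = generate_episodes(cfg, registers)

persons = registers.groupby("practice_id")["count"].sum()
print(f"practices:          {cfg.n_practices}")
print(f"registered adults:  {persons.sum():,} "
      f"(practice sizes {persons.min():,}-{persons.max():,})")
print(f"episodes:           {len(episodes):,} over {len(cfg.years)} years")
print(f"procedures:         {(episodes.event_class == 'procedure').mean():.1%}"
      " of episodes")

# Each practice's deprivation score is the register-weighted mean IMD decile
# (1 = most deprived): a noisy, practice-level proxy for the deprivation of
# the patients themselves.
scores = registers.drop_duplicates("practice_id")["deprivation_score"]
print(f"practice deprivation scores: {scores.min():.1f}-{scores.max():.1f}")
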