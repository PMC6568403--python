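# Desk-scale configuration for synthetic experiments on a single CPU.
chromosome_length: 5
population_size: 50
max_generations: 60
k: 5
n_sets: 50
fitness_threshold: 0.9
mutation_rate: 0.05
crossover_rate: 0.9
elitism_count: 2
standardize: true
seed: 0
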