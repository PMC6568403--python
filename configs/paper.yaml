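# Full-scale GA/KNN configuration: 20-gene chromosomes, population 300,
# up to 1000 generations, 5-NN majority vote, 5000 collected sets per
# training partition.
chromosome_length: 20
population_size: 300
max_generations: 1000
k: 5
n_sets: 5000
fitness_threshold: 0.95
mutation_rate: 0.05
crossover_rate: 0.9
elitism_count: 2
standardize: true
seed: 0
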