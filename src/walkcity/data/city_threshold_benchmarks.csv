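city,income_group,pct_pop_density_A,pct_pop_density_B,pct_int_density_A,pct_int_density_B
Maiduguri,middle,98.0,95.9,45.6,28.5
Mexico City,middle,98.9,98.1,89.6,78.6
Baltimore,high,39.6,28.0,64.8,51.7
Phoenix,high,30.1,15.7,74.4,51.0
Seattle,high,10.9,6.4,61.3,43.2
Sao Paulo,middle,99.6,99.4,88.0,70.4
Hong Kong,high,98.3,97.7,95.7,91.5
Chennai,middle,99.8,99.7,90.4,79.3
Bangkok,middle,98.2,97.0,61.5,39.7
Hanoi,middle,95.7,93.0,67.6,56.3
Adelaide,high,3.7,0.0,38.4,12.6
Melbourne,high,33.4,17.8,37.8,20.8
Sydney,high,67.5,51.0,24.9,13.4
Auckland,high,47.9,22.3,26.6,14.5
Graz,high,64.0,44.1,92.5,81.3
Ghent,high,0.0,0.0,67.5,54.8
Olomouc,high,0.0,0.0,69.0,54.2
Odense,high,6.0,0.0,94.8,85.3
Cologne,high,47.5,21.6,83.9,71.6
Lisbon,high,98.1,96.8,99.7,98.6
Barcelona,high,95.5,92.3,82.6,74.9
Valencia,high,97.8,95.8,78.6,72.3
Vic,high,47.1,24.3,65.3,56.4
Bern,high,82.1,58.3,99.3,98.2
Belfast,high,59.6,40.1,91.1,74.0
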