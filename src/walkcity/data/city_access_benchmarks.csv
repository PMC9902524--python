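city,country,region,income_group,pct_food_market,pct_convenience,pct_pt_stop_any,pct_pt_stop_30min,pct_pt_stop_20min,pct_pos_any_entry,pct_pos_large_entry,pm25_transport_tpa
Maiduguri,Nigeria,Africa,middle,17.4,27.4,9.6,,,1.9,0.5,7.5
Mexico City,Mexico,North America,middle,26.4,22.7,35.8,24.7,19.7,49.6,19.7,532.0
Baltimore,USA,North America,high,14.3,29.1,63.1,51.3,42.8,62.5,39.2,324.8
Phoenix,USA,North America,high,5.6,21.0,66.0,61.6,24.1,36.5,24.6,268.3
Seattle,USA,North America,high,15.5,26.1,60.3,36.3,26.6,59.2,35.0,316.3
Sao Paulo,Brazil,South America,middle,35.2,36.7,96.1,95.7,94.2,71.7,15.5,2306.5
Hong Kong,Hong Kong,Asia,high,48.9,52.2,89.5,86.9,83.6,86.9,54.1,1903.7
Chennai,India,Asia,middle,19.7,15.6,39.1,3.2,3.2,41.1,11.3,657.9
Bangkok,Thailand,Asia,middle,15.3,33.4,63.0,62.1,43.2,14.1,6.5,4163.9
Hanoi,Vietnam,Asia,middle,38.0,46.4,65.5,21.9,11.2,26.7,14.1,2062.8
Adelaide,Australia,Australasia,high,18.8,19.9,89.2,81.9,53.7,87.3,58.0,147.4
Melbourne,Australia,Australasia,high,20.7,29.6,86.7,67.2,49.4,88.2,63.3,1364.0
Sydney,Australia,Australasia,high,22.3,28.7,94.7,78.4,57.7,90.1,60.3,564.8
Auckland,New Zealand,Australasia,high,31.2,47.9,91.0,81.4,55.7,90.6,64.9,340.3
Graz,Austria,Europe,high,62.6,56.4,92.2,,,84.9,39.5,14.4
Ghent,Belgium,Europe,high,49.5,44.1,86.5,,,92.7,62.7,47.4
Olomouc,Czech Republic,Europe,high,37.2,43.7,88.8,,,90.4,46.0,2.6
Odense,Denmark,Europe,high,43.7,36.1,84.4,66.1,59.0,92.9,73.4,3.9
Cologne,Germany,Europe,high,51.1,56.9,79.0,71.7,60.2,89.6,65.8,158.9
Lisbon,Portugal,Europe,high,64.2,60.7,97.0,95.7,92.8,90.1,51.3,208.1
Barcelona,Spain,Europe,high,63.8,61.6,91.4,78.3,75.8,88.2,62.8,186.1
Valencia,Spain,Europe,high,59.7,48.4,81.6,78.3,77.2,78.4,43.8,105.0
Vic,Spain,Europe,high,50.7,40.1,57.7,,,81.4,74.8,
Bern,Switzerland,Europe,high,69.3,73.5,94.8,93.6,91.8,98.9,80.0,10.3
Belfast,UK,Europe,high,29.0,47.8,92.9,82.9,72.6,65.0,46.8,29.4
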