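cell_id,frame,z_index,x_px,y_px,amplitude,background,score_db,round
fixture_field,0,-1,34.525119967861968,61.492606693906374,37129.864342676221,147.81103650522323,113.25672562939017,0
fixture_field,0,-1,26.771657369086974,35.292602780213087,27023.258936529481,153.76796179909351,235.93986537754634,0
fixture_field,0,-1,64.820861828858597,33.204839596731901,21686.933910697888,165.18050574302268,283.3899752834177,0
fixture_field,0,-1,86,53,21069.294295169446,153.64818329893154,440.71481372330618,0
fixture_field,0,-1,69.197279239696996,47.563435116477706,20377.86377808539,151.98906994655994,186.08056815928066,0
fixture_field,0,-1,109,50,19272.422013248088,152.99932403863869,303.01012693112904,0
fixture_field,0,-1,92.611022388211637,58.121262973826695,19107.116495655184,150.01851842567257,217.36354801093415,0
fixture_field,0,-1,39.88051029016296,32.489374867248181,19001.800322940311,157.19649698383549,176.72486591682994,0
fixture_field,0,-1,63.459428560291251,75.996913037873696,18381.137388549439,152.05882494174526,193.55860976805553,0
fixture_field,0,-1,44.879763346526723,88.16675618855983,17961.433383278545,156.24865740736922,276.34142537382399,0
fixture_field,0,-1,91.137129448170441,26.45116915994879,17078.606880104773,113.14168852451147,189.65876758116178,0
fixture_field,0,-1,84.121088342263533,23.374552563090841,16040.537743889679,127.03365318499168,220.24443450497245,0
fixture_field,0,-1,79.07403392844023,40.156295697277244,15736.21008294421,155.55181301380557,370.53586407272758,0
fixture_field,0,-1,96.589412600265163,53.536808941319848,15529.510406924965,153.60419212163086,137.02741378107231,0
fixture_field,0,-1,75.135260094345341,33.853380055302004,15297.754653204007,145.5234782248493,346.0460375486266,0
fixture_field,0,-1,58.598920380731997,29.688900212416236,13734.611462871551,156.65237566974912,174.25721804624123,0
fixture_field,0,-1,56,91,13292.659323308239,182.61285654998193,165.26807625320237,0
fixture_field,0,-1,23.521485893304753,50.969518898986628,12647.754083867208,152.27190415160598,184.51867095817789,0
fixture_field,0,-1,57,58,12207.702236880461,187.24055587790502,163.50170453899918,0
fixture_field,0,-1,67,31,12060.878731995394,149.47520055984648,265.0784283214208,1
fixture_field,0,-1,15.063839783110273,65.699757053953775,12018.159707631105,148.90727692545119,270.62553431967694,0
fixture_field,0,-1,19.529729139802548,43.180430476982124,10887.910418907508,140.38190141572568,175.2358003810846,0
fixture_field,0,-1,42.472036640853766,66.462203488816201,10754.938117574817,145.82531575881825,123.99687040175232,0
fixture_field,0,-1,43.728301749707448,46.171732364399197,10389.427011624222,157.40631568989494,262.46257173271687,0
fixture_field,0,-1,90.66616576499743,54.112088039394813,10389.090137954116,142.93922966619161,233.78011409382694,0
fixture_field,0,-1,88,84,10246.864459402967,159.81702992132404,237.56898494779745,0
fixture_field,0,-1,15.66186307975358,57.633408169265905,9491.9998648392793,153.52805715842669,177.15694381909316,0
fixture_field,0,-1,84.305784415658664,54.970620849917132,9362.1664651893279,164.36793639999561,221.91189539482917,1
fixture_field,0,-1,74.059858107758856,85.16197579926876,9137.2226273752658,156.59701114363781,364.2149669072262,0
fixture_field,0,-1,77.107176740778499,81.850579362460678,8920.1174066750791,151.54589474950387,353.67406359424814,0
fixture_field,0,-1,46.894048548068085,89.191047307813648,8709.809429017896,147.08663443706985,214.67363279332818,1
fixture_field,0,-1,63.285598524849107,44.475985461824685,8607.6209725988283,159.3960563849563,158.03008913306468,0
fixture_field,0,-1,43.37131917130128,87.754082767969962,7631.3196158858091,131.07367337029956,144.74863798558445,1
fixture_field,0,-1,75.864144922330397,48.851213944881898,7561.7759221565093,154.23499418889844,345.0092661413666,0
fixture_field,0,-1,84.544240893313287,52.063298176971799,5234.1880801944353,142.07458652262815,112.26885825969867,2
fixture_field,0,-1,36,61,3283.9756013540841,146.48137006359121,51.186123628245625,1
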