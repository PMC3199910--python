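cat_score,rank,description
40,1,Cannot move far from bed or chair
40,2,Have become frail or an invalid
40,3,Cannot do housework
35,1,Cannot take bath/shower or takes a long time
35,2,Breathless walking around the home
35,3,Chest trouble has become a nuisance to friends/relatives
30,1,Everything seems too much of an effort
30,2,No good days in the week
30,3,Stops patient doing most of what they want to do
25,1,Feel that not in control of chest problem
25,2,Cough/breathing disturbs sleep
25,3,Get afraid or panic when cannot get breath
20,1,Wheeze worse in the morning
20,2,Breathless on bending over
20,3,Wheezing attacks on most days
15,1,Cough several days a week
15,2,Breathlessness on most days
15,3,Housework takes a long time or have to take rests
10,1,Usually cannot play sports or games
10,2,Gets exhausted easily
10,3,Walk slower than other people or stop for rests
5,1,Breathlessness stops patient doing one or two things
5,2,Chest condition causes a few problems
5,3,Breathless walking up hills
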